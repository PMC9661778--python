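import numpy as np
import pytest
from scipy.spatial import Delaunay

from pa4dflow.containers import TimeResolvedMesh
from pa4dflow.geometry import CrossSection
from pa4dflow.synthetic import PhantomSpec, disc_triangulation, make_phantom


def _orient(nodes, tets):
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    neg = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return tets


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Tetrahedralised unit cube (volume exactly 1), one frame."""
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                       dtype=float)
    tets = _orient(corners, Delaunay(corners).simplices.astype(np.int64))
    return TimeResolvedMesh(
        connectivity=tets, nodes_per_frame=corners[None],
        frame_times=np.array([0.0]))


@pytest.fixture(scope="session")
def coarse_tube():
    """Small steady Poiseuille tube phantom (coarse, fast)."""
    spec = PhantomSpec(case="poiseuille", radius=1.0, length=3.0,
                       element_size=0.25, spacing=0.15, frames=4, u_max=40.0)
    mesh, cl, field, subject = make_phantom(spec)
    return spec, mesh, cl, field, subject


@pytest.fixture(scope="session")
def solid_body_tube():
    spec = PhantomSpec(case="solid_body", rotation_rate=2.0, radius=1.0,
                       length=3.0, element_size=0.25, spacing=0.15, frames=4)
    mesh, cl, field, subject = make_phantom(spec)
    return spec, mesh, cl, field, subject


def make_disc_slice(R=1.0, h=0.08, profile=None):
    """Planar disc cross-section at z=0 with an analytic velocity profile."""
    pts2d, tris = disc_triangulation(R, h)
    verts = np.column_stack([pts2d, np.zeros(len(pts2d))])
    a, b, c = (verts[tris[:, i]] for i in range(3))
    area = float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
    xsec = CrossSection(origin=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
                        vertices=verts, triangles=tris, area=area, fraction=0.5)
    if profile is not None:
        r = np.hypot(verts[:, 0], verts[:, 1])
        uz = profile(r)
        xsec.velocities = np.column_stack([np.zeros((len(verts), 2)), uz])
    return xsec
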