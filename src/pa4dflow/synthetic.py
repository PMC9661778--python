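"""Analytic flow phantoms with known ground-truth metric values.

The generator builds tetrahedral tube and Y-junction meshes (Delaunay disc
triangulation extruded into conforming prism splits), exact centerlines,
and voxelised analytic velocity fields (Poiseuille, solid-body rotation,
helical, simple shear, Dean-like counter-rotating pair, pulsating tube),
together with synthetic subject records.  Ground-truth metric values come
from closed forms or independent dense quadrature of the analytic field,
never from the pipeline itself.

Default conditions mirror a typical 4D-flow acquisition: 1.2 mm tetrahedral
elements, 1.0 mm voxels, 20 cardiac frames over a 1 s cycle, venc
300 cm/s.  Identical specs (including seed) yield identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.spatial import Delaunay

from .containers import (
    CenterlineSet,
    SubjectRecord,
    TimeResolvedMesh,
    VelocityField4D,
)

CASES = ("poiseuille", "helical", "dean_pair", "pulsating_tube",
         "y_junction", "shear", "solid_body")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one analytic phantom."""

    case: str = "poiseuille"
    # geometry (cm)
    radius: float = 1.0
    length: float = 10.0
    curvature_radius: float = np.inf      # finite -> torus-segment tube
    element_size: float = 0.12
    # flow parameters
    u_max: float = 40.0                   # cm/s, peak axial velocity
    axial_velocity: float = 1.0           # cm/s, plug/helical W
    rotation_rate: float = 1.0            # 1/s, solid-body Omega
    shear_rate: float = 3.0               # 1/s, gamma
    vortex_strength: float = 10.0         # 1/s, Dean-pair streamfunction scale
    pulsation: float = 0.1                # delta, radial pulsation amplitude
    # time
    frames: int = 4
    period: float = 1.0                   # s
    t_systole: float = 0.4                # s, systolic duration for pulsatile flow
    # grid
    spacing: float = 0.1                  # cm voxels
    margin: float = 0.5                   # cm beyond the mesh bounding box
    venc: float = 300.0                   # cm/s
    noise_pct: float = 0.0                # Gaussian sigma as % of venc
    seed: int = 0
    # Y-junction extras
    daughter_radius: float = 0.75
    parent_length: float = 6.0
    daughter_length: float = 5.0
    branch_angle_deg: float = 40.0
    flow_split: tuple[float, float] = (0.5, 0.5)
    outflow_scale: float = 1.0            # < 1 deliberately violates conservation

    def __post_init__(self):
        if self.case not in CASES:
            raise ValueError(f"unknown phantom case {self.case!r}")
        if self.element_size <= 0:
            raise ValueError("element size must be positive")
        time_resolved = self.case in ("pulsating_tube",)
        if time_resolved and self.frames < 4:
            raise ValueError("time-resolved phantoms need at least 4 frames")
        if np.isfinite(self.curvature_radius) and \
                self.curvature_radius <= self.radius:
            raise ValueError("torus tube needs curvature radius > tube radius")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.frames) * self.period / self.frames


# ---------------------------------------------------------------------------
# meshing


def _disc_points(R: float, h: float) -> tuple[np.ndarray, int]:
    """Boundary n-gon + interior hexagonal lattice covering a disc."""
    n_b = max(12, int(round(2 * np.pi * R / h)))
    ang = 2 * np.pi * np.arange(n_b) / n_b
    boundary = np.stack([R * np.cos(ang), R * np.sin(ang)], axis=1)
    pts = [boundary]
    dy = h * np.sqrt(3) / 2
    j = 0
    rows = int(np.ceil(R / dy)) + 1
    for j in range(-rows, rows + 1):
        y = j * dy
        x0 = 0.0 if j % 2 == 0 else h / 2
        nx = int(np.ceil((R + h) / h))
        xs = x0 + h * np.arange(-nx, nx + 1)
        row = np.stack([xs, np.full_like(xs, y)], axis=1)
        keep = np.hypot(row[:, 0], row[:, 1]) < R - 0.35 * h
        pts.append(row[keep])
    return np.concatenate(pts), n_b


def disc_triangulation(R: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Counter-clockwise triangulation of a disc of radius R (cm)."""
    pts, _ = _disc_points(R, h)
    tri = Delaunay(pts).simplices
    a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    ab, ac = b - a, c - a
    s = ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0]
    flip = s < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return pts, tri


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
]


def _split_prism(v: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Split a triangular prism into 3 tets with globally conforming quad
    diagonals (indirection rule keyed on the smallest global node index)."""
    vmin = min(v)
    for p in _PRISM_ROTATIONS:
        w = [v[i] for i in p]
        if w[0] == vmin:
            break
    if min(w[1], w[5]) < min(w[2], w[4]):
        return [(w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]),
                (w[0], w[4], w[5], w[3])]
    return [(w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]),
            (w[0], w[4], w[5], w[3])]


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    neg = vol6 < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return tets


def _boundary_triangles(tets: np.ndarray) -> np.ndarray:
    faces = np.concatenate([
        tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
        tets[:, [0, 2, 3]], tets[:, [1, 2, 3]],
    ])
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key, faces = key[order], faces[order]
    dup_prev = np.concatenate([[False], np.all(key[1:] == key[:-1], axis=1)])
    dup_next = np.concatenate([np.all(key[1:] == key[:-1], axis=1), [False]])
    return faces[~(dup_prev | dup_next)]


def _extruded_tube(R: float, L: float, h: float):
    """Straight tube along +z, z in [0, L]; returns (nodes, tets, surface,
    caps) with caps 'z0' (z=0) and 'z1' (z=L)."""
    pts2d, tri2d = disc_triangulation(R, h)
    n2d = len(pts2d)
    n_layers = max(2, int(round(L / h)))
    zs = np.linspace(0.0, L, n_layers + 1)
    nodes = np.concatenate([
        np.column_stack([pts2d, np.full(n2d, z)]) for z in zs
    ])
    tets = []
    for k in range(n_layers):
        lo, hi = k * n2d, (k + 1) * n2d
        for t in tri2d:
            prism = np.array([lo + t[0], lo + t[1], lo + t[2],
                              hi + t[0], hi + t[1], hi + t[2]])
            tets.extend(_split_prism(prism))
    tets = _fix_orientation(nodes, np.array(tets, dtype=np.int64))
    surface = _boundary_triangles(tets)
    z_face = nodes[surface][:, :, 2]
    caps = {
        "z0": np.nonzero(np.all(np.abs(z_face) < 1e-9, axis=1))[0],
        "z1": np.nonzero(np.all(np.abs(z_face - L) < 1e-9, axis=1))[0],
    }
    return nodes, tets, surface, caps


def _bend_to_torus(nodes: np.ndarray, Rc: float) -> np.ndarray:
    """Map a straight tube along +z onto a torus segment of radius Rc.

    The centerline z -> phi = z/Rc traces p(phi) = Rc (cos phi - 1, 0,
    sin phi); tube x maps to the in-plane radial offset, y stays axial.
    """
    x, y, z = nodes.T
    phi = z / Rc
    return np.column_stack([
        (Rc + x) * np.cos(phi) - Rc, y, (Rc + x) * np.sin(phi),
    ])


def _rotation_to(v: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z onto the unit vector v (Rodrigues)."""
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(z @ v)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    k = np.cross(z, v)
    s = np.linalg.norm(k)
    k = k / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def make_tube(spec: PhantomSpec) -> tuple[TimeResolvedMesh, CenterlineSet]:
    """Tube phantom mesh + exact centerline.

    Straight for infinite curvature radius, torus segment otherwise; the
    pulsating_tube case scales the cross-section per frame as
    r(t) = R (1 + delta sin(2 pi t / T)).
    """
    R, L, h = spec.radius, spec.length, spec.element_size
    nodes, tets, surface, caps = _extruded_tube(R, L, h)
    times = spec.frame_times

    n_cl = 50
    if np.isfinite(spec.curvature_radius):
        Rc = spec.curvature_radius
        nodes = _bend_to_torus(nodes, Rc)
        phi = np.linspace(0, L / Rc, n_cl)
        cl = np.column_stack([Rc * (np.cos(phi) - 1), np.zeros(n_cl),
                              Rc * np.sin(phi)])
    else:
        cl = np.column_stack([np.zeros((n_cl, 2)), np.linspace(0, L, n_cl)])

    if spec.case == "pulsating_tube":
        scale = 1 + spec.pulsation * np.sin(2 * np.pi * times / spec.period)
        frames = []
        for s in scale:
            f = nodes.copy()
            f[:, :2] *= s       # radial pulsation about the straight axis
            frames.append(f)
        nodes_pf = np.stack(frames)
    else:
        nodes_pf = np.broadcast_to(nodes, (len(times), *nodes.shape)).copy()

    mesh = TimeResolvedMesh(
        connectivity=tets, nodes_per_frame=nodes_pf, frame_times=times,
        surface=surface,
        cap_faces={"MPA": caps["z0"], "outlet": caps["z1"]},
    )
    centerlines = CenterlineSet(
        branches={"MPA": cl}, radii={"MPA": np.full(n_cl, R)})
    return mesh, centerlines


# ---------------------------------------------------------------------------
# analytic velocity fields


def _segment_distance(pts, a, b):
    d = b - a
    t = np.clip(((pts - a) @ d) / (d @ d), 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


def field_evaluator(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic velocity u(x) (cm/s) for the phantom case, at points (cm).

    Every case is the smooth analytic formula over all space (the mesh, not
    the field, defines the vessel), so interpolation and differentiation
    are tested against the exact field with no wall discontinuity.
    """
    R = spec.radius

    if spec.case in ("poiseuille", "pulsating_tube"):
        def u(pts, radius=R):
            pts = np.atleast_2d(pts)
            r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
            out = np.zeros_like(pts)
            out[:, 2] = spec.u_max * (1 - r2 / radius ** 2)
            return out
        return u

    if spec.case == "solid_body":
        def u(pts):
            pts = np.atleast_2d(pts)
            w = spec.rotation_rate
            return np.column_stack([-w * pts[:, 1], w * pts[:, 0],
                                    np.zeros(len(pts))])
        return u

    if spec.case == "helical":
        def u(pts):
            pts = np.atleast_2d(pts)
            w = spec.rotation_rate
            return np.column_stack([-w * pts[:, 1], w * pts[:, 0],
                                    np.full(len(pts), spec.axial_velocity)])
        return u

    if spec.case == "shear":
        def u(pts):
            pts = np.atleast_2d(pts)
            return np.column_stack([spec.shear_rate * pts[:, 1],
                                    np.zeros(len(pts)), np.zeros(len(pts))])
        return u

    if spec.case == "dean_pair":
        # streamfunction psi = s x exp(-(x^2+y^2)/(2 sigma^2)) is odd in x,
        # giving two mirror-image in-plane vortices; H_d is exactly mirror-
        # antisymmetric so the positive-helicity volume fraction is 1/2.
        sigma = R / 2.0
        s = spec.vortex_strength

        def u(pts):
            pts = np.atleast_2d(pts)
            x, y = pts[:, 0], pts[:, 1]
            e = np.exp(-(x ** 2 + y ** 2) / (2 * sigma ** 2))
            ux = s * x * (-y / sigma ** 2) * e            # d psi / d y
            uy = -s * (1 - x ** 2 / sigma ** 2) * e       # -d psi / d x
            return np.column_stack([ux, uy,
                                    np.full(len(pts), spec.axial_velocity)])
        return u

    raise ValueError(f"no single-tube field for case {spec.case!r}")


def field_curl(spec: PhantomSpec, pts: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Curl of the analytic field by central finite differences (oracle)."""
    u = field_evaluator(spec)
    pts = np.atleast_2d(pts)

    def d(comp, axis):
        e = np.zeros(3)
        e[axis] = h
        return (u(pts + e)[:, comp] - u(pts - e)[:, comp]) / (2 * h)

    return np.column_stack([
        d(2, 1) - d(1, 2), d(0, 2) - d(2, 0), d(1, 0) - d(0, 1),
    ])


def _temporal_scale(spec: PhantomSpec) -> np.ndarray:
    """Per-frame flow scaling: half-sine systolic waveform for pulsatile
    cases, unity for steady cases."""
    if spec.case == "pulsating_tube":
        t = spec.frame_times
        s = np.where(t < spec.t_systole,
                     np.sin(np.pi * t / np.maximum(spec.t_systole, 1e-12)), 0.0)
        return s
    return np.ones(spec.frames)


def make_field(spec: PhantomSpec, mesh_bbox: Optional[np.ndarray] = None,
               ) -> VelocityField4D:
    """Voxelise the analytic field on a regular grid covering the mesh.

    The grid is node-centred with the spec's spacing (cm) and margin;
    optional Gaussian noise (sigma = noise_pct% of venc) is seeded from the
    spec for reproducibility.
    """
    if spec.case == "y_junction":
        return _y_junction_field(spec, mesh_bbox)
    R, L = spec.radius, spec.length
    if mesh_bbox is None:
        if spec.case == "pulsating_tube":
            rmax = R * (1 + spec.pulsation)
        else:
            rmax = R
        mesh_bbox = np.array([[-rmax, -rmax, 0.0], [rmax, rmax, L]])
        if np.isfinite(spec.curvature_radius):
            Rc = spec.curvature_radius
            phi = L / Rc
            xs = (Rc + R) * np.cos(np.linspace(0, phi, 64)) - Rc
            zs = (Rc + R) * np.sin(np.linspace(0, phi, 64))
            mesh_bbox = np.array([
                [min(xs.min(), -R), -R, min(zs.min(), 0)],
                [max(xs.max(), R), R, max(zs.max(), L)],
            ])
    lo = mesh_bbox[0] - spec.margin
    hi = mesh_bbox[1] + spec.margin
    dims = np.maximum(2, np.ceil((hi - lo) / spec.spacing).astype(int) + 1)
    if 2 * spec.radius / spec.spacing < 6:
        warnings.warn("velocity grid is coarse: fewer than 6 voxels across "
                      "the tube diameter", stacklevel=2)
    axes = [lo[i] + spec.spacing * np.arange(dims[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    scale = _temporal_scale(spec)
    times = spec.frame_times
    vel = np.empty((spec.frames, *dims, 3))
    if spec.case == "pulsating_tube":
        radii = R * (1 + spec.pulsation * np.sin(2 * np.pi * times / spec.period))
        base_eval = field_evaluator(spec)
        for f in range(spec.frames):
            vals = base_eval(pts, radius=radii[f]) * scale[f]
            vel[f] = vals.reshape(*dims, 3)
    else:
        vals = field_evaluator(spec)(pts)
        for f in range(spec.frames):
            vel[f] = (vals * scale[f]).reshape(*dims, 3)

    if spec.noise_pct > 0:
        rng = np.random.default_rng(spec.seed)
        vel = vel + rng.normal(0.0, spec.noise_pct / 100.0 * spec.venc, vel.shape)

    return VelocityField4D(
        origin=lo * 10.0, spacing=np.full(3, spec.spacing * 10.0),
        dims=tuple(dims), frame_times=times, velocities=vel,
        period=spec.period, venc=spec.venc,
    )


# ---------------------------------------------------------------------------
# Y-junction


def _y_junction_axes(spec: PhantomSpec):
    th = np.deg2rad(spec.branch_angle_deg)
    J = np.array([0.0, 0.0, spec.parent_length])
    d_l = np.array([-np.sin(th), 0.0, np.cos(th)])
    d_r = np.array([np.sin(th), 0.0, np.cos(th)])
    return J, d_l, d_r


def _y_junction_umax(spec: PhantomSpec) -> tuple[float, float, float]:
    q_parent = spec.u_max * np.pi * spec.radius ** 2 / 2.0
    q_out = spec.outflow_scale * q_parent
    split = np.asarray(spec.flow_split, float)
    split = split / split.sum()
    u_d = [2.0 * (q_out * s) / (np.pi * spec.daughter_radius ** 2) for s in split]
    return spec.u_max, u_d[0], u_d[1]


def make_y_junction(spec: PhantomSpec,
                    ) -> tuple[TimeResolvedMesh, CenterlineSet, VelocityField4D]:
    """Symmetric planar Y-junction phantom with mass-conserving Poiseuille
    flow (parent flow = sum of daughter flows, scaled by ``outflow_scale``).

    Caps are labelled MPA (parent inflow), LPA and RPA (daughter outflows);
    centerlines are ordered from each cap toward the junction.
    """
    J, d_l, d_r = _y_junction_axes(spec)
    # daughters overlap if their axes stay closer than 2 r_d at the far caps
    far_sep = np.linalg.norm((J + spec.daughter_length * d_l)
                             - (J + spec.daughter_length * d_r))
    if far_sep < 2 * spec.daughter_radius:
        raise ValueError("daughter branches overlap: increase angle or length")

    h = spec.element_size
    parent_spec = (spec.radius, spec.parent_length)
    nodes_p, tets_p, surf_p, caps_p = _extruded_tube(*parent_spec, h)
    nodes_d, tets_d, surf_d, caps_d = _extruded_tube(
        spec.daughter_radius, spec.daughter_length, h)

    all_nodes, all_tets, all_surf = [nodes_p], [tets_p], [surf_p]
    cap_faces = {"MPA": caps_p["z0"]}
    n_nodes, n_faces = len(nodes_p), len(surf_p)
    for label, d in (("LPA", d_l), ("RPA", d_r)):
        Rm = _rotation_to(-d)
        placed = (J + spec.daughter_length * d) + nodes_d @ Rm.T
        all_nodes.append(placed)
        all_tets.append(tets_d + n_nodes)
        all_surf.append(surf_d + n_nodes)
        cap_faces[label] = caps_d["z0"] + n_faces
        n_nodes += len(nodes_d)
        n_faces += len(surf_d)
    nodes = np.concatenate(all_nodes)
    tets = _fix_orientation(nodes, np.concatenate(all_tets))
    surface = np.concatenate(all_surf)

    times = spec.frame_times
    mesh = TimeResolvedMesh(
        connectivity=tets,
        nodes_per_frame=np.broadcast_to(nodes, (len(times), *nodes.shape)).copy(),
        frame_times=times, surface=surface, cap_faces=cap_faces,
    )

    n_cl = 40
    s = np.linspace(0, 1, n_cl)[:, None]
    cl = {
        "MPA": (1 - s) * np.zeros(3) + s * J,
        "LPA": (1 - s) * (J + spec.daughter_length * d_l) + s * J,
        "RPA": (1 - s) * (J + spec.daughter_length * d_r) + s * J,
    }
    radii = {
        "MPA": np.full(n_cl, spec.radius),
        "LPA": np.full(n_cl, spec.daughter_radius),
        "RPA": np.full(n_cl, spec.daughter_radius),
    }
    centerlines = CenterlineSet(branches=cl, radii=radii)
    fieldv = _y_junction_field(spec, np.array([nodes.min(0), nodes.max(0)]))
    return mesh, centerlines, fieldv


def _y_junction_velocity(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Piecewise Poiseuille field: each point follows its nearest branch axis."""
    J, d_l, d_r = _y_junction_axes(spec)
    u_p, u_l, u_r = _y_junction_umax(spec)
    origin = np.zeros(3)
    axes = [
        (origin, J, np.array([0.0, 0.0, 1.0]), spec.radius, u_p),
        (J, J + spec.daughter_length * d_l, d_l, spec.daughter_radius, u_l),
        (J, J + spec.daughter_length * d_r, d_r, spec.daughter_radius, u_r),
    ]
    pts = np.atleast_2d(pts)
    dists = np.stack([_segment_distance(pts, a, b) for a, b, *_ in axes])
    nearest = np.argmin(dists, axis=0)
    out = np.zeros_like(pts)
    for k, (a, b, direction, radius, umax) in enumerate(axes):
        m = nearest == k
        if not m.any():
            continue
        prof = umax * (1 - (dists[k][m] / radius) ** 2)
        out[m] = prof[:, None] * direction
    return out


def _y_junction_field(spec: PhantomSpec, mesh_bbox) -> VelocityField4D:
    lo = np.asarray(mesh_bbox[0], float) - spec.margin
    hi = np.asarray(mesh_bbox[1], float) + spec.margin
    dims = np.maximum(2, np.ceil((hi - lo) / spec.spacing).astype(int) + 1)
    axes = [lo[i] + spec.spacing * np.arange(dims[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vals = _y_junction_velocity(spec, pts).reshape(*dims, 3)
    times = spec.frame_times
    vel = np.broadcast_to(vals, (spec.frames, *vals.shape)).copy()
    if spec.noise_pct > 0:
        rng = np.random.default_rng(spec.seed)
        vel = vel + rng.normal(0.0, spec.noise_pct / 100.0 * spec.venc, vel.shape)
    return VelocityField4D(
        origin=lo * 10.0, spacing=np.full(3, spec.spacing * 10.0),
        dims=tuple(dims), frame_times=times, velocities=vel,
        period=spec.period, venc=spec.venc,
    )


def make_phantom(spec: PhantomSpec):
    """One-stop constructor: (mesh, centerlines, field, subject record)."""
    if spec.case == "y_junction":
        mesh, cl, fieldv = make_y_junction(spec)
    else:
        mesh, cl = make_tube(spec)
        fieldv = make_field(spec)
    return mesh, cl, fieldv, phantom_subject(spec)


def phantom_subject(spec: PhantomSpec) -> SubjectRecord:
    """Synthetic subject record with typical demographics and pressures."""
    t_ed, t_es = (0.0, spec.t_systole) if spec.case == "pulsating_tube" else (None, None)
    return SubjectRecord(
        id=f"phantom-{spec.case}", timepoint="pre", sex="M", age=62.0,
        height=171.0, weight=76.0, spap=25.0, dpap=15.0, mpap=18.0,
        rvef=55.0, rvedv=180.0, rvesv=80.0, rvsv=100.0,
        t_ed=t_ed, t_es=t_es,
    )


# ---------------------------------------------------------------------------
# ground truth


def ground_truth(spec: PhantomSpec, n_samples: int = 1_000_000,
                 seed: Optional[int] = None) -> dict[str, float]:
    """Reference metric values for an analytic case.

    Integral quantities (mean vorticity, HFI, helicity fractions) come from
    dense Monte-Carlo quadrature of the analytic field and its
    finite-difference curl over the tube volume -- fully independent of the
    pipeline's mesh, interpolation and FEM gradients.  Scalar identities
    (flow, Q, RAC, Dean number) use closed forms.
    """
    if spec.case == "y_junction":
        q_parent = spec.u_max * np.pi * spec.radius ** 2 / 2.0
        return {
            "flow_mpa": q_parent,
            "flow_lpa": spec.outflow_scale * spec.flow_split[0] * q_parent
            / sum(spec.flow_split),
            "flow_rpa": spec.outflow_scale * spec.flow_split[1] * q_parent
            / sum(spec.flow_split),
            "conservation_error": abs(1 - spec.outflow_scale),
        }

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    R, L = spec.radius, spec.length
    r = R * np.sqrt(rng.random(n_samples))
    th = 2 * np.pi * rng.random(n_samples)
    z = L * rng.random(n_samples)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
    u = field_evaluator(spec)(pts)
    w = field_curl(spec, pts)
    speed = np.linalg.norm(u, axis=1)
    wmag = np.linalg.norm(w, axis=1)
    h_d = np.einsum("ij,ij->i", u, w)
    ok = speed * wmag > 1e-9
    out = {
        "vorticity_vectormean": float(np.linalg.norm(w.mean(axis=0))),
        "vorticity_magmean": float(wmag.mean()),
        "helicity_fraction_positive": float(np.mean(h_d > 0)),
        "hfi": float(np.mean(np.abs(h_d[ok]) / (speed[ok] * wmag[ok]))) if ok.any() else 0.0,
        "helicity_mean": float(h_d.mean()),
        "volume": np.pi * R ** 2 * L,
        "n_samples": float(n_samples),
    }
    if spec.case in ("poiseuille", "pulsating_tube"):
        out["flow"] = spec.u_max * np.pi * R ** 2 / 2.0
        out["centerline_velocity"] = spec.u_max
        out["reverse_flow_fraction"] = 0.0
        out["q_criterion"] = 0.0
    if spec.case == "pulsating_tube":
        d = spec.pulsation
        out["rac"] = 4 * d / (1 - d) ** 2
    if spec.case == "solid_body":
        out["q_criterion"] = spec.rotation_rate ** 2
        out["h_d"] = 0.0
    if spec.case == "helical":
        out["h_d"] = 2.0 * spec.rotation_rate * spec.axial_velocity
        W, Om = abs(spec.axial_velocity), abs(spec.rotation_rate)
        out["hfi_closed_form"] = (
            2 * W / (Om ** 2 * R ** 2) * (np.sqrt(W ** 2 + Om ** 2 * R ** 2) - W))
    if spec.case == "shear":
        out["q_criterion"] = 0.0
    return out
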