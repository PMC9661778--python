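"""Velocity sampling and discrete differential operators on tet meshes.

Velocities from the regular acquisition grid are resampled onto mesh nodes
and slice vertices by trilinear interpolation.  Spatial derivatives use the
linear shape functions of each tetrahedron, giving a piecewise-constant
velocity-gradient tensor that is exact for affine fields; vorticity, the
strain-rate/rotation split and the Q-criterion all derive from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .containers import MM_PER_CM, TimeResolvedMesh, VelocityField4D
from .geometry import CrossSection


@dataclass
class NodeField:
    """Per-node velocity vectors (cm/s) on one mesh frame."""

    mesh: TimeResolvedMesh
    frame: int
    values: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_nodes, 3):
            raise ValueError("need one 3-vector per mesh node")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("node field contains non-finite values")

    def element_velocities(self) -> np.ndarray:
        """Centroid velocity per element (mean of the 4 node values)."""
        return self.values[self.mesh.connectivity].mean(axis=1)


@dataclass
class GradientField:
    """Per-element velocity-gradient tensor G_ij = du_i/dx_j (1/s)."""

    mesh: TimeResolvedMesh
    frame: int
    grad: np.ndarray  # (M, 3, 3)

    @property
    def strain(self) -> np.ndarray:
        """Symmetric strain-rate tensor S = (G + G^T)/2."""
        return 0.5 * (self.grad + np.swapaxes(self.grad, 1, 2))

    @property
    def rotation(self) -> np.ndarray:
        """Antisymmetric rotation tensor Omega = (G - G^T)/2."""
        return 0.5 * (self.grad - np.swapaxes(self.grad, 1, 2))

    @property
    def vorticity(self) -> np.ndarray:
        """Curl of the velocity per element, (M, 3) in 1/s."""
        g = self.grad
        return np.stack([
            g[:, 2, 1] - g[:, 1, 2],
            g[:, 0, 2] - g[:, 2, 0],
            g[:, 1, 0] - g[:, 0, 1],
        ], axis=1)


def _interpolators(fieldv: VelocityField4D, vframe: int, fill_value):
    axes = fieldv.axes_mm()
    return [
        RegularGridInterpolator(
            axes, fieldv.velocities[vframe, ..., c],
            bounds_error=fill_value is None, fill_value=fill_value)
        for c in range(3)
    ]


def _nearest_velocity_frame(fieldv: VelocityField4D, t: float) -> int:
    return int(np.argmin(np.abs(fieldv.frame_times - t)))


def sample_at_points(fieldv: VelocityField4D, points_cm: np.ndarray,
                     time: float, time_mode: str = "nearest",
                     fill: str = "error") -> np.ndarray:
    """Trilinear velocity samples (cm/s) at world points (cm) and a time (s).

    ``time_mode`` 'nearest' picks the closest velocity frame; 'linear'
    blends the two bracketing frames.  ``fill`` 'error' rejects points
    outside the grid, 'zero' fills them with a warning.
    """
    pts_mm = np.asarray(points_cm, dtype=float) * MM_PER_CM
    fill_value = None if fill == "error" else 0.0

    def _one_frame(vframe):
        interps = _interpolators(fieldv, vframe, fill_value)
        try:
            return np.stack([ip(pts_mm) for ip in interps], axis=-1)
        except ValueError as exc:
            raise ValueError(
                "mesh/slice points fall outside the velocity grid "
                "(set fill='zero' to zero-fill)") from exc

    if time_mode == "nearest" or fieldv.n_frames == 1:
        out = _one_frame(_nearest_velocity_frame(fieldv, time))
    elif time_mode == "linear":
        t = np.clip(time, fieldv.frame_times[0], fieldv.frame_times[-1])
        k = int(np.searchsorted(fieldv.frame_times, t, side="right") - 1)
        k = min(max(k, 0), fieldv.n_frames - 2)
        t0, t1 = fieldv.frame_times[k], fieldv.frame_times[k + 1]
        w = (t - t0) / (t1 - t0)
        out = (1 - w) * _one_frame(k) + w * _one_frame(k + 1)
    else:
        raise ValueError(f"unknown time_mode {time_mode!r}")

    if fill_value is not None:
        lo = np.array([a[0] for a in fieldv.axes_mm()])
        hi = np.array([a[-1] for a in fieldv.axes_mm()])
        outside = np.any((pts_mm < lo) | (pts_mm > hi), axis=-1)
        n_out = int(np.count_nonzero(outside))
        if n_out:
            warnings.warn(f"{n_out} points outside velocity grid zero-filled",
                          stacklevel=2)
    return out


def resample_to_mesh(fieldv: VelocityField4D, mesh: TimeResolvedMesh,
                     frame: int, time_mode: str = "nearest",
                     fill: str = "error") -> NodeField:
    """Sample the grid velocities at the mesh nodes of one frame."""
    t = mesh.frame_times[frame]
    values = sample_at_points(fieldv, mesh.nodes_per_frame[frame], t,
                              time_mode=time_mode, fill=fill)
    return NodeField(mesh=mesh, frame=frame, values=values)


def sample_on_slice(fieldv: VelocityField4D, xsec: CrossSection, time: float,
                    time_mode: str = "nearest", fill: str = "error") -> CrossSection:
    """Fill a cross-section's per-vertex velocities from the grid field."""
    xsec.velocities = sample_at_points(fieldv, xsec.vertices, time,
                                       time_mode=time_mode, fill=fill)
    return xsec


def velocity_gradient(nodefield: NodeField) -> GradientField:
    """Per-element constant velocity gradient from linear shape functions.

    Exact (to round-off) for affine fields u = A x + b on any nondegenerate
    tetrahedral mesh.
    """
    mesh = nodefield.mesh
    x = mesh.nodes_per_frame[nodefield.frame]
    conn = mesh.connectivity
    E = x[conn[:, 1:]] - x[conn[:, :1]]          # (M, 3, 3) edge rows
    U = nodefield.values[conn[:, 1:]] - nodefield.values[conn[:, :1]]
    det = np.linalg.det(E)
    if np.any(np.abs(det) < 1e-14):
        bad = int(np.argmin(np.abs(det)))
        raise ValueError(f"degenerate tetrahedron {bad} (zero volume)")
    grad_t = np.linalg.solve(E, U)               # solves E G^T = U
    return GradientField(mesh=mesh, frame=nodefield.frame,
                         grad=np.swapaxes(grad_t, 1, 2))


def q_criterion(gradfield: GradientField) -> np.ndarray:
    """Q = (||Omega||_F^2 - ||S||_F^2)/2 per element (1/s^2); Q > 0 marks
    rotation-dominated fluid."""
    S = gradfield.strain
    O = gradfield.rotation
    return 0.5 * (np.sum(O * O, axis=(1, 2)) - np.sum(S * S, axis=(1, 2)))


def branch_vorticity(gradfield: GradientField, element_ids,
                     mode: str = "vector-mean") -> float:
    """Volume-averaged vorticity over a branch (1/s).

    'vector-mean' returns |(1/V) integral of curl u dV| (the literal
    spatial-average formula, which cancels for symmetric swirl);
    'magnitude-mean' returns (1/V) integral of |curl u| dV.
    """
    ids = np.asarray(element_ids, dtype=int)
    if ids.size == 0:
        raise ValueError("empty branch")
    vols = gradfield.mesh.tet_volumes(gradfield.frame)[ids]
    omega = gradfield.vorticity[ids]
    V = vols.sum()
    if mode == "vector-mean":
        return float(np.linalg.norm((vols[:, None] * omega).sum(axis=0) / V))
    if mode == "magnitude-mean":
        return float((vols * np.linalg.norm(omega, axis=1)).sum() / V)
    raise ValueError(f"unknown vorticity mode {mode!r}")


@dataclass
class VortexRegion:
    element_ids: np.ndarray
    volume: float


def _face_adjacency(conn: np.ndarray, subset: np.ndarray):
    """Sparse adjacency between elements of ``subset`` sharing a facet."""
    faces = np.concatenate([
        conn[subset][:, [0, 1, 2]], conn[subset][:, [0, 1, 3]],
        conn[subset][:, [0, 2, 3]], conn[subset][:, [1, 2, 3]],
    ])
    owner = np.tile(np.arange(len(subset)), 4)
    faces = np.sort(faces, axis=1)
    order = np.lexsort(faces.T)
    faces, owner = faces[order], owner[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    i, j = owner[:-1][same], owner[1:][same]
    n = len(subset)
    return coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))


def detect_vortex_regions(gradfield: GradientField, nodefield: NodeField,
                          speed_threshold: float = 30.0) -> list[VortexRegion]:
    """Connected vortex candidate regions: Q > 0 and slow flow.

    Elements with Q > 0 whose centroid speed is below ``speed_threshold``
    (cm/s, default 30) are grouped into face-connected components; each
    region reports its element ids and volume.
    """
    q = q_criterion(gradfield)
    speed = np.linalg.norm(nodefield.element_velocities(), axis=1)
    mask = (q > 0) & (speed < speed_threshold)
    subset = np.nonzero(mask)[0]
    if subset.size == 0:
        return []
    adj = _face_adjacency(gradfield.mesh.connectivity, subset)
    n_comp, labels = connected_components(adj, directed=False)
    vols = gradfield.mesh.tet_volumes(gradfield.frame)
    regions = []
    for k in range(n_comp):
        ids = subset[labels == k]
        regions.append(VortexRegion(element_ids=ids, volume=float(vols[ids].sum())))
    regions.sort(key=lambda r: -r.volume)
    return regions
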