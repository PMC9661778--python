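"""Vessel geometry operations: keyframe interpolation, branch splitting,
perpendicular cross-sections at fractional arc length, volumes and
centerline curvature.

Branch regions follow the anatomic convention: every tetrahedron is assigned
to the branch whose centerline is nearest, except elements inside the
bifurcation region (a ball around the point where the daughter centerlines
meet the parent centerline), which are flagged and excluded from all
per-branch metrics.  Arc-length fractions are measured from the cap end of
each branch (fraction 0 at the inflow/outflow cap, 1 at the bifurcation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .containers import CenterlineSet, TimeResolvedMesh


# ---------------------------------------------------------------------------
# keyframe interpolation


def default_alpha_schedule(frame_times, t_min: float, t_max: float,
                           period: float) -> np.ndarray:
    """Clipped cosine blending weight between the min- and max-volume keyframes.

    alpha rises smoothly 0 -> 1 from t_min to t_max, then falls back to 0
    over the remainder of the cycle (cyclic), so the vessel distends and
    relaxes once per cardiac period.
    """
    t = np.asarray(frame_times, dtype=float)
    rise = (t_max - t_min) % period
    phase = (t - t_min) % period
    alpha = np.empty_like(t)
    up = phase <= rise
    alpha[up] = 0.5 * (1 - np.cos(np.pi * phase[up] / rise))
    fall = period - rise
    alpha[~up] = 0.5 * (1 + np.cos(np.pi * (phase[~up] - rise) / fall))
    return np.clip(alpha, 0.0, 1.0)


def interpolate_keyframes(mesh_min: TimeResolvedMesh, mesh_max: TimeResolvedMesh,
                          frame_times, alpha=None,
                          t_min: Optional[float] = None,
                          t_max: Optional[float] = None,
                          period: Optional[float] = None) -> TimeResolvedMesh:
    """Linearly blend two node-corresponded keyframe meshes over the cycle.

    Node positions are x(t) = (1 - alpha(t)) x_min + alpha(t) x_max; frames
    with alpha 0 / 1 reproduce the keyframes exactly.  When ``alpha`` is not
    given it follows :func:`default_alpha_schedule` between ``t_min`` and
    ``t_max``.
    """
    if mesh_min.n_nodes != mesh_max.n_nodes:
        raise ValueError("keyframe meshes must have identical node counts")
    if not np.array_equal(mesh_min.connectivity, mesh_max.connectivity):
        raise ValueError("keyframe meshes must share connectivity")
    frame_times = np.asarray(frame_times, dtype=float)
    if alpha is None:
        if t_min is None or t_max is None or period is None:
            raise ValueError("provide either alpha or (t_min, t_max, period)")
        alpha = default_alpha_schedule(frame_times, t_min, t_max, period)
    alpha = np.asarray(alpha, dtype=float)
    x0 = mesh_min.nodes_per_frame[0]
    x1 = mesh_max.nodes_per_frame[0]
    nodes = (1 - alpha)[:, None, None] * x0 + alpha[:, None, None] * x1
    return TimeResolvedMesh(
        connectivity=mesh_min.connectivity, nodes_per_frame=nodes,
        frame_times=frame_times, surface=mesh_min.surface,
        cap_faces=dict(mesh_min.cap_faces),
    )


# ---------------------------------------------------------------------------
# volumes


def mesh_volume(mesh: TimeResolvedMesh, frame: int = 0,
                element_ids=None) -> float:
    """Total (or per-branch) tetrahedral volume in cm^3 at a frame."""
    vols = mesh.tet_volumes(frame)
    if element_ids is not None:
        vols = vols[np.asarray(element_ids, dtype=int)]
    total = float(np.sum(vols))
    if total < 0:
        raise ValueError("mesh has negative total volume (orientation error)")
    return total


def element_centroids(mesh: TimeResolvedMesh, frame: int = 0) -> np.ndarray:
    x = mesh.nodes_per_frame[frame]
    return x[mesh.connectivity].mean(axis=1)


# ---------------------------------------------------------------------------
# branch splitting

BIFURCATION_LABEL = "__bifurcation__"


@dataclass
class BranchRegion:
    """Elements belonging to one branch (or the excluded bifurcation region)."""

    label: str
    element_ids: np.ndarray
    centerline_label: Optional[str] = None
    cap_label: Optional[str] = None
    is_bifurcation: bool = False


def _polyline_tree(pts: np.ndarray, resolution: float = 0.05) -> cKDTree:
    """KD-tree on a densely resampled polyline for point-to-curve distances."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dense = [pts[:1]]
    for i, L in enumerate(seg):
        n = max(1, int(np.ceil(L / resolution)))
        s = np.linspace(0, 1, n + 1)[1:, None]
        dense.append(pts[i] * (1 - s) + pts[i + 1] * s)
    return cKDTree(np.concatenate(dense))


def find_bifurcation_point(centerlines: CenterlineSet, parent: str = "MPA",
                           radius: Optional[float] = None) -> tuple[np.ndarray, float]:
    """Locate the bifurcation: where daughter centerlines first approach the
    parent centerline within one local inscribed radius (or ``radius``).

    Daughters are walked from their cap end (point 0) toward the junction.
    Returns (point, radius used).
    """
    daughters = [l for l in centerlines.labels if l != parent]
    tree = _polyline_tree(centerlines.points(parent))
    approach = []
    r_used = []
    for lab in daughters:
        pts = centerlines.points(lab)
        radii = centerlines.radii.get(lab)
        d, _ = tree.query(pts)
        for i in range(len(pts)):
            r = radius if radius is not None else (
                float(radii[i]) if radii is not None else None)
            if r is None:
                raise ValueError(
                    "no inscribed radii on centerlines; pass an explicit radius")
            if d[i] <= r:
                approach.append(pts[i])
                r_used.append(r)
                break
        else:
            approach.append(pts[-1])
            r_used.append(radius if radius is not None else float(radii[-1]))
    return np.mean(approach, axis=0), float(np.mean(r_used))


def split_branches(mesh: TimeResolvedMesh, centerlines: CenterlineSet,
                   frame: int = 0, bifurcation_radius: Optional[float] = None,
                   ) -> list[BranchRegion]:
    """Assign every tetrahedron to its nearest branch centerline.

    With more than one branch, elements whose centroid lies within the
    bifurcation ball are flagged and excluded from all branches.  Raises if a
    centerline lies entirely outside the mesh.
    """
    cent = element_centroids(mesh, frame)
    labels = centerlines.labels
    dists = np.empty((len(labels), len(cent)))
    for k, lab in enumerate(labels):
        tree = _polyline_tree(centerlines.points(lab))
        dists[k], _ = tree.query(cent)
        # a centerline entirely outside the mesh never comes near any centroid
        if dists[k].min() > 2.0:
            raise ValueError(f"centerline {lab!r} appears to lie outside the mesh")
    nearest = np.argmin(dists, axis=0)

    bif_mask = np.zeros(len(cent), dtype=bool)
    if len(labels) > 1:
        parent = "MPA" if "MPA" in labels else labels[0]
        bif_pt, r_bif = find_bifurcation_point(
            centerlines, parent=parent, radius=bifurcation_radius)
        bif_mask = np.linalg.norm(cent - bif_pt, axis=1) <= r_bif

    regions = []
    for k, lab in enumerate(labels):
        ids = np.nonzero((nearest == k) & ~bif_mask)[0]
        cap = lab if lab in mesh.cap_faces else None
        regions.append(BranchRegion(label=lab, element_ids=ids,
                                    centerline_label=lab, cap_label=cap))
    if bif_mask.any():
        regions.append(BranchRegion(
            label=BIFURCATION_LABEL, element_ids=np.nonzero(bif_mask)[0],
            is_bifurcation=True))
    return regions


# ---------------------------------------------------------------------------
# cross-sections


@dataclass
class CrossSection:
    """Planar slice through the mesh, perpendicular to the centerline.

    ``vertices`` (cm) all lie on the plane; ``triangles`` index them;
    ``velocities`` (cm/s) are filled in by the field-sampling stage.
    """

    origin: np.ndarray
    normal: np.ndarray
    vertices: np.ndarray
    triangles: np.ndarray
    area: float
    fraction: float
    branch: Optional[str] = None
    velocities: Optional[np.ndarray] = None

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def flip(self) -> None:
        """Reverse the slice normal (forward-flow orientation)."""
        self.normal = -self.normal


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return pts
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([pts[:1].repeat(pad, 0), pts, pts[-1:].repeat(pad, 0)])
    return np.stack([np.convolve(padded[:, i], kernel, mode="valid")
                     for i in range(3)], axis=1)


def centerline_tangent(centerlines: CenterlineSet, label: str,
                       fraction: float, smooth_window: int = 5) -> np.ndarray:
    """Unit tangent of the (smoothed) centerline at an arc-length fraction."""
    pts = _smooth_polyline(centerlines.points(label), smooth_window)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    d1 = np.gradient(pts, s, axis=0)
    target = fraction * s[-1]
    t = np.array([np.interp(target, s, d1[:, i]) for i in range(3)])
    return t / np.linalg.norm(t)


def slice_at_fraction(mesh: TimeResolvedMesh, centerlines: CenterlineSet,
                      branch: str, fraction: float, frame: int = 0,
                      smooth_window: int = 5) -> CrossSection:
    """Cross-section perpendicular to a branch centerline at a fraction of
    its arc length (measured from the cap end).

    The plane-tetrahedron intersection is computed by marching tetrahedra;
    only the connected intersection component containing the centerline
    point is kept.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if centerlines.total_length(branch) <= 0:
        raise ValueError(f"branch {branch!r} has zero centerline length")
    origin = centerlines.point_at_fraction(branch, fraction)
    normal = centerline_tangent(centerlines, branch, fraction, smooth_window)
    xsec = slice_plane(mesh, origin, normal, frame=frame, near_point=origin)
    xsec.fraction = fraction
    xsec.branch = branch
    return xsec


def slice_plane(mesh: TimeResolvedMesh, origin: np.ndarray, normal: np.ndarray,
                frame: int = 0, near_point: Optional[np.ndarray] = None,
                ) -> CrossSection:
    """Intersect the tet mesh with a plane; keep the component nearest
    ``near_point`` (default: the plane origin)."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    origin = np.asarray(origin, dtype=float)
    if near_point is None:
        near_point = origin
    x = mesh.nodes_per_frame[frame]

    # nudge the plane until no node sits exactly on it (degenerate cuts)
    offset = 0.0
    sd = (x - origin) @ normal
    while np.any(np.abs(sd) < 1e-9):
        offset += 1e-7
        sd = (x - origin) @ normal - offset
    plane_origin = origin + offset * normal

    conn = mesh.connectivity
    s_tet = sd[conn]
    crossing = np.nonzero((s_tet.min(axis=1) < 0) & (s_tet.max(axis=1) > 0))[0]
    if crossing.size == 0:
        raise ValueError("plane does not intersect the mesh")

    edge_pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    vert_index: dict[tuple[int, int], int] = {}
    verts: list[np.ndarray] = []
    polys: list[list[int]] = []
    poly_edges: list[list[tuple[int, int]]] = []

    for e in crossing:
        nodes = conn[e]
        s = sd[nodes]
        cut_ids, cut_edges = [], []
        for i, j in edge_pairs:
            if (s[i] < 0) != (s[j] < 0):
                a, b = int(nodes[i]), int(nodes[j])
                key = (a, b) if a < b else (b, a)
                idx = vert_index.get(key)
                if idx is None:
                    t = s[i] / (s[i] - s[j])
                    verts.append(x[nodes[i]] + t * (x[nodes[j]] - x[nodes[i]]))
                    idx = len(verts) - 1
                    vert_index[key] = idx
                cut_ids.append(idx)
                cut_edges.append(key)
        if len(cut_ids) < 3:
            continue
        if len(cut_ids) == 4:
            # order quad vertices by angle around their centroid in-plane
            pts = np.array([verts[i] for i in cut_ids])
            c = pts.mean(axis=0)
            e1 = pts[0] - c
            e1 -= (e1 @ normal) * normal
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(normal, e1)
            ang = np.arctan2((pts - c) @ e2, (pts - c) @ e1)
            order = np.argsort(ang)
            cut_ids = [cut_ids[k] for k in order]
        polys.append(cut_ids)
        poly_edges.append(cut_edges)

    # union-find over polygons sharing a cut edge -> connected components
    parent = list(range(len(polys)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_owner: dict[tuple[int, int], int] = {}
    for p, edges in enumerate(poly_edges):
        for key in edges:
            if key in edge_owner:
                ra, rb = find(edge_owner[key]), find(p)
                parent[ra] = rb
            else:
                edge_owner[key] = p

    verts_arr = np.array(verts)
    comp_of = np.array([find(p) for p in range(len(polys))])
    # component containing near_point: smallest distance from polygon centroid
    best_comp, best_d = None, np.inf
    for p, ids in enumerate(polys):
        d = np.linalg.norm(verts_arr[ids].mean(axis=0) - near_point)
        if d < best_d:
            best_d, best_comp = d, comp_of[p]

    triangles = []
    keep_vert: dict[int, int] = {}
    new_verts: list[np.ndarray] = []
    for p, ids in enumerate(polys):
        if comp_of[p] != best_comp:
            continue
        mapped = []
        for i in ids:
            if i not in keep_vert:
                keep_vert[i] = len(new_verts)
                new_verts.append(verts_arr[i])
            mapped.append(keep_vert[i])
        for k in range(1, len(mapped) - 1):
            triangles.append((mapped[0], mapped[k], mapped[k + 1]))

    vertices = np.array(new_verts)
    triangles = np.array(triangles, dtype=np.int64)
    a, b, c = (vertices[triangles[:, i]] for i in range(3))
    area = float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
    if area <= 0:
        raise ValueError("empty plane-mesh intersection")
    return CrossSection(origin=plane_origin, normal=normal, vertices=vertices,
                        triangles=triangles, area=area, fraction=np.nan)


# ---------------------------------------------------------------------------
# curvature


def centerline_curvature(centerlines: CenterlineSet, label: str,
                         fraction: float, smooth_window: int = 5) -> float:
    """Radius of curvature R_c (cm) of a branch centerline at a fraction of
    its arc length: kappa = |r' x r''| / |r'|^3 from finite differences of
    the smoothed, arc-length-parameterised polyline.  Straight segments
    return +inf.
    """
    pts = centerlines.points(label)
    if len(pts) < 5:
        raise ValueError("curvature needs at least 5 centerline points")
    pts = _smooth_polyline(pts, smooth_window)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    d1 = np.gradient(pts, s, axis=0)
    d2 = np.gradient(d1, s, axis=0)
    kappa = (np.linalg.norm(np.cross(d1, d2), axis=1)
             / np.maximum(np.linalg.norm(d1, axis=1) ** 3, 1e-300))
    target = fraction * s[-1]
    # interior interpolation; gradient end-points are one-sided and noisier
    k = float(np.interp(target, s[2:-2], kappa[2:-2])) if len(s) > 8 else float(
        np.interp(target, s, kappa))
    if k < 1e-12:
        return np.inf
    return 1.0 / k
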