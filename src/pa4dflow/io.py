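"""Readers and writers for velocity fields, meshes, centerlines and tables.

Velocity volumes travel as NIfTI in two dialects: one scalar volume per
component per frame, or a single 5-D volume indexed (x, y, z, frame,
component).  Either way a YAML sidecar declares frame times, period, units
and the component order (x, y, z in world axes).  Meshes are ascii .vtu
(tetrahedra + labelled boundary triangles), centerlines ascii .vtp, subject
records and metric tables CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import vtkxml
from .containers import (
    METRICS_COLUMNS,
    CenterlineSet,
    MetricsTable,
    SubjectRecord,
    TimeResolvedMesh,
    VelocityField4D,
)

_VELOCITY_UNIT_TO_CMS = {"cm/s": 1.0, "m/s": 100.0, "mm/s": 0.1}
_LENGTH_UNIT_TO_CM = {"cm": 1.0, "mm": 0.1, "m": 100.0}


def convert_velocity(values: np.ndarray, from_units: str, to_units: str = "cm/s") -> np.ndarray:
    """Convert velocity values between cm/s, m/s and mm/s (involutive)."""
    try:
        factor = _VELOCITY_UNIT_TO_CMS[from_units] / _VELOCITY_UNIT_TO_CMS[to_units]
    except KeyError as exc:
        raise ValueError(f"unknown velocity unit {exc}") from None
    return np.asarray(values) * factor


def _check_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    """Return (origin_mm, spacing_mm) from an axis-aligned NIfTI affine."""
    rot = affine[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-8):
        raise ValueError(f"{path}: only axis-aligned (diagonal) affines are supported")
    spacing = np.diag(rot).copy()
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine must have positive spacings")
    return affine[:3, 3].copy(), spacing


def read_velocity_series(paths, metadata) -> VelocityField4D:
    """Read a time-resolved velocity field from NIfTI volumes.

    Parameters
    ----------
    paths
        Either a nested sequence ``paths[frame][component]`` of per-frame
        per-component scalar NIfTI files, or a single path to a 5-D NIfTI
        indexed (x, y, z, frame, component).
    metadata
        Mapping (or path to a YAML file) with keys ``frame_times`` (s),
        ``period`` (s), ``velocity_units`` and optional ``venc`` (cm/s).
        Components are ordered x, y, z in world axes.
    """
    if isinstance(metadata, (str, Path)):
        with open(metadata) as fh:
            metadata = yaml.safe_load(fh)
    frame_times = np.asarray(metadata["frame_times"], dtype=float)
    units = metadata.get("velocity_units", "cm/s")
    venc = metadata.get("venc")

    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 5 or data.shape[4] != 3:
            raise ValueError(f"{paths}: expected 5-D (x,y,z,frame,component) volume")
        origin, spacing = _check_affine(img.affine, paths)
        if data.shape[3] != len(frame_times):
            raise ValueError(
                f"{paths}: {data.shape[3]} frames in volume but "
                f"{len(frame_times)} frame times declared"
            )
        vel = np.moveaxis(data, 3, 0)  # (T, x, y, z, comp)
    else:
        paths = [list(p) for p in paths]
        if len(paths) != len(frame_times):
            raise ValueError(
                f"{len(paths)} frame file groups but {len(frame_times)} frame times"
            )
        origin = spacing = None
        frames = []
        for group in paths:
            if len(group) != 3:
                raise ValueError("each frame needs exactly 3 component volumes")
            comps = []
            for p in group:
                img = nib.load(str(p))
                o, s = _check_affine(img.affine, p)
                arr = np.asarray(img.dataobj, dtype=float)
                if arr.ndim != 3:
                    raise ValueError(f"{p}: component volume must be 3-D")
                if origin is None:
                    origin, spacing, shape0 = o, s, arr.shape
                elif (np.any(np.abs(o - origin) > 1e-6)
                      or np.any(np.abs(s - spacing) > 1e-6)
                      or arr.shape != shape0):
                    raise ValueError(f"{p}: grid geometry differs between volumes")
                comps.append(arr)
            frames.append(np.stack(comps, axis=-1))
        vel = np.stack(frames, axis=0)

    vel = convert_velocity(vel, units)
    field = VelocityField4D(
        origin=origin, spacing=spacing, dims=vel.shape[1:4],
        frame_times=frame_times, velocities=vel,
        period=float(metadata["period"]),
        venc=float(venc) if venc is not None else None,
    )
    n_bad = field.venc_violations()
    if n_bad:
        warnings.warn(
            f"{n_bad} velocity samples exceed venc={field.venc} cm/s",
            stacklevel=2,
        )
    return field


def write_velocity_series(field: VelocityField4D, out_dir, stem: str = "velocity",
                          dialect: str = "5d") -> dict:
    """Write a velocity field as NIfTI (+ YAML sidecar); returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(field.spacing)
    affine[:3, 3] = field.origin
    written: dict = {"metadata": str(out_dir / f"{stem}.yaml")}
    if dialect == "5d":
        data = np.moveaxis(field.velocities, 0, 3)
        path = out_dir / f"{stem}.nii"
        nib.save(nib.Nifti1Image(data, affine), str(path))
        written["volumes"] = str(path)
    elif dialect == "per-frame":
        files = []
        for t in range(field.n_frames):
            group = []
            for c, name in enumerate("xyz"):
                path = out_dir / f"{stem}_{name}_f{t:03d}.nii"
                nib.save(nib.Nifti1Image(field.velocities[t, ..., c], affine), str(path))
                group.append(str(path))
            files.append(group)
        written["volumes"] = files
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = {
        "frame_times": [float(t) for t in field.frame_times],
        "period": float(field.period),
        "velocity_units": "cm/s",
        "component_order": "xyz (world axes)",
    }
    if field.venc is not None:
        meta["venc"] = float(field.venc)
    with open(written["metadata"], "w") as fh:
        yaml.safe_dump(meta, fh)
    return written


def read_mesh_series(paths: Sequence, frame_times=None,
                     length_units: str = "cm") -> TimeResolvedMesh:
    """Read per-frame .vtu meshes sharing connectivity into one container.

    Each file holds the tetrahedra, boundary triangles, and (optionally) an
    integer ``cap_label`` cell array on the triangles; labels are mapped to
    names through a ``cap_names`` entry in the first file's companion JSON
    sidecar (``<file>.caps.json``) when present, else ``cap_<k>``.
    """
    paths = [Path(p) for p in paths]
    meshes = [vtkxml.read_vtu(p) for p in paths]
    ref = meshes[0]
    scale = _LENGTH_UNIT_TO_CM[length_units]
    n_nodes = len(ref["points"])
    for p, m in zip(paths[1:], meshes[1:]):
        if len(m["points"]) != n_nodes:
            raise ValueError(f"{p}: node count differs from first frame")
        if not np.array_equal(m["tets"], ref["tets"]):
            raise ValueError(f"{p}: connectivity differs from first frame")
    nodes = np.stack([m["points"] * scale for m in meshes])
    if frame_times is None:
        frame_times = np.arange(len(paths), dtype=float)

    cap_faces: dict[str, np.ndarray] = {}
    if "cap_label" in ref["cell_data"]:
        labels = np.asarray(ref["cell_data"]["cap_label"][1], dtype=int).ravel()
        names = {}
        sidecar = paths[0].with_suffix(paths[0].suffix + ".caps.json")
        if sidecar.exists():
            names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        for lab in np.unique(labels):
            if lab < 0:
                continue
            cap_faces[names.get(int(lab), f"cap_{lab}")] = np.nonzero(labels == lab)[0]

    mesh = TimeResolvedMesh(
        connectivity=ref["tets"], nodes_per_frame=nodes,
        frame_times=np.asarray(frame_times, dtype=float),
        surface=ref["triangles"], cap_faces=cap_faces,
    )
    mesh.validate()
    return mesh


def write_mesh_series(mesh: TimeResolvedMesh, out_dir, stem: str = "mesh") -> list[str]:
    """Write one ascii .vtu per frame plus a cap-name sidecar; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cap_label = np.full(len(mesh.surface), -1, dtype=np.int64)
    names = {}
    for k, (name, faces) in enumerate(sorted(mesh.cap_faces.items())):
        cap_label[np.asarray(faces, int)] = k
        names[k] = name
    paths = []
    for f in range(mesh.n_frames):
        path = out_dir / f"{stem}_f{f:03d}.vtu"
        vtkxml.write_vtu(
            path, mesh.nodes_per_frame[f], mesh.connectivity,
            triangles=mesh.surface,
            cell_data={"cap_label": np.concatenate([
                np.full(mesh.n_elements, -1, np.int64), cap_label])},
        )
        paths.append(str(path))
    sidecar = Path(paths[0]).with_suffix(".vtu.caps.json")
    sidecar.write_text(json.dumps(names))
    return paths


def read_centerlines(path, labels: Optional[Sequence[str]] = None,
                     length_units: str = "cm") -> CenterlineSet:
    """Read branch centerlines from an ascii .vtp of polylines.

    Branch names come from, in order of precedence: the ``labels`` argument,
    a ``<path>.labels.json`` sidecar (list of names in line order), or the
    default MPA/LPA/RPA/branch_<k> sequence.  Duplicate consecutive points
    are removed with a warning.
    """
    path = Path(path)
    data = vtkxml.read_vtp(path)
    scale = _LENGTH_UNIT_TO_CM[length_units]
    pts = data["points"] * scale
    if labels is None:
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        if sidecar.exists():
            labels = json.loads(sidecar.read_text())
        else:
            defaults = ["MPA", "LPA", "RPA"]
            labels = [defaults[i] if i < 3 else f"branch_{i}"
                      for i in range(len(data["lines"]))]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate branch labels: {labels}")
    if len(labels) != len(data["lines"]):
        raise ValueError("label count does not match number of polylines")

    branches, radii = {}, {}
    radius_arr = data["point_data"].get("radius")
    for label, idx in zip(labels, data["lines"]):
        line = pts[idx]
        keep = np.concatenate([[True], np.linalg.norm(np.diff(line, axis=0), axis=1) > 0])
        if not keep.all():
            warnings.warn(
                f"centerline {label!r}: removed {np.count_nonzero(~keep)} "
                "duplicate consecutive points", stacklevel=2)
        line = line[keep]
        if len(line) < 3:
            raise ValueError(f"centerline {label!r} has fewer than 3 distinct points")
        branches[label] = line
        if radius_arr is not None:
            radii[label] = np.asarray(radius_arr).ravel()[idx][keep] * scale
    return CenterlineSet(branches=branches, radii=radii)


def write_centerlines(cl: CenterlineSet, path) -> None:
    path = Path(path)
    all_pts, lines, radii = [], [], []
    offset = 0
    for label in cl.labels:
        pts = cl.points(label)
        all_pts.append(pts)
        lines.append(np.arange(offset, offset + len(pts)))
        radii.append(cl.radii.get(label, np.zeros(len(pts))))
        offset += len(pts)
    point_data = {"radius": np.concatenate(radii)} if cl.radii else None
    vtkxml.write_vtp(path, np.concatenate(all_pts), lines, point_data=point_data)
    path.with_suffix(path.suffix + ".labels.json").write_text(json.dumps(cl.labels))


def read_subjects(path) -> list[SubjectRecord]:
    """Read a subject record CSV (one row per subject-timepoint)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    records = []
    for _, row in df.iterrows():
        kwargs = {"id": str(row["id"])}
        for col in ("timepoint", "sex"):
            if col in row and pd.notna(row[col]):
                kwargs[col] = str(row[col])
        for col in ("age", "height", "weight", "spap", "dpap", "mpap", "tpr",
                    "rvef", "rvedv", "rvesv", "rvsv", "t_ed", "t_es"):
            if col in row and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        records.append(SubjectRecord(**kwargs))
    return records


def write_subjects(records: Sequence[SubjectRecord], path) -> None:
    pd.DataFrame([r.as_dict() for r in records]).to_csv(path, index=False)


def write_metrics_table(table: MetricsTable, path) -> None:
    """Write a MetricsTable as CSV with fixed column order."""
    table.validate()
    cols = METRICS_COLUMNS + [c for c in table.df.columns if c not in METRICS_COLUMNS]
    table.df[cols].to_csv(path, index=False, float_format="%.12g")


def read_metrics_table(path) -> MetricsTable:
    df = pd.read_csv(path)
    if len(df) == 0:
        df = pd.DataFrame(columns=METRICS_COLUMNS)
    return MetricsTable(df)
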