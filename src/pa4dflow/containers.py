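"""Core data containers for the 4D-flow post-processing pipeline.

Unit conventions used throughout the package:

* lengths in cm (mesh nodes, centerlines, slice geometry),
* velocity-grid geometry (origin, spacing) in mm, matching NIfTI affines,
* velocities in cm/s, time in s, pressure in mmHg,
* flow reported in cm^3/s and L/min (1 cm^3/s = 0.06 L/min).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MM_PER_CM = 10.0
CM3S_PER_LMIN = 1.0 / 0.06  # 1 L/min = 16.67 cm^3/s
LMIN_PER_CM3S = 0.06


@dataclass
class VelocityField4D:
    """Time-resolved velocity vector field sampled on a regular grid.

    ``velocities`` is indexed ``(frame, x, y, z, component)`` in cm/s; the
    grid geometry (``origin``, ``spacing``) is in mm in world axes, with the
    samples treated as node-centred at ``origin + index * spacing``.
    """

    origin: np.ndarray          # (3,) mm
    spacing: np.ndarray         # (3,) mm
    dims: tuple[int, int, int]
    frame_times: np.ndarray     # (T,) s, strictly increasing, < period
    velocities: np.ndarray      # (T, nx, ny, nz, 3) cm/s
    period: float               # s
    venc: Optional[float] = None  # cm/s

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        self.validate()

    def validate(self) -> None:
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be strictly positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid must have at least 2 samples per axis")
        if self.velocities.shape != (len(self.frame_times), *self.dims, 3):
            raise ValueError(
                f"velocity array shape {self.velocities.shape} inconsistent with "
                f"{len(self.frame_times)} frames and dims {self.dims}"
            )
        dt = np.diff(self.frame_times)
        if len(self.frame_times) > 1 and np.any(dt <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.frame_times >= self.period):
            raise ValueError("all frame times must lie within one cardiac period")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
            for i in range(3)
        )

    def venc_violations(self) -> int:
        """Number of samples whose component magnitude exceeds venc."""
        if self.venc is None:
            return 0
        return int(np.count_nonzero(np.abs(self.velocities) > self.venc))


@dataclass
class TimeResolvedMesh:
    """Tetrahedral mesh with fixed connectivity and per-frame node positions.

    ``connectivity`` is (M, 4) node indices with positive signed volume at
    every frame; ``nodes_per_frame`` is (T, N, 3) in cm.  ``surface`` holds
    boundary triangles and ``cap_faces`` labels disjoint subsets of them
    (inlet/outlet caps such as MPA, LPA, RPA).
    """

    connectivity: np.ndarray               # (M, 4) int
    nodes_per_frame: np.ndarray            # (T, N, 3) cm
    frame_times: np.ndarray                # (T,) s
    surface: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    cap_faces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.connectivity = np.asarray(self.connectivity, dtype=np.int64)
        self.nodes_per_frame = np.asarray(self.nodes_per_frame, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.surface = np.asarray(self.surface, dtype=np.int64).reshape(-1, 3)
        if self.nodes_per_frame.ndim != 3 or self.nodes_per_frame.shape[2] != 3:
            raise ValueError("nodes_per_frame must have shape (frames, nodes, 3)")

    @property
    def n_frames(self) -> int:
        return self.nodes_per_frame.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes_per_frame.shape[1]

    @property
    def n_elements(self) -> int:
        return self.connectivity.shape[0]

    def nodes(self, frame: int) -> np.ndarray:
        return self.nodes_per_frame[frame]

    def tet_volumes(self, frame: int) -> np.ndarray:
        """Signed tetrahedron volumes (cm^3) at a frame."""
        x = self.nodes_per_frame[frame]
        a, b, c, d = (x[self.connectivity[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def validate(self) -> None:
        if np.any(self.connectivity < 0) or np.any(self.connectivity >= self.n_nodes):
            raise ValueError("connectivity references nodes outside the mesh")
        for f in range(self.n_frames):
            vols = self.tet_volumes(f)
            bad = np.nonzero(vols <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"element {bad[0]} has non-positive volume at frame {f}"
                )
        seen: set[int] = set()
        for label, faces in self.cap_faces.items():
            faces = np.asarray(faces, dtype=int)
            if seen.intersection(faces.tolist()):
                raise ValueError(f"cap face set {label!r} overlaps another cap")
            seen.update(faces.tolist())
            if faces.size and faces.max() >= len(self.surface):
                raise ValueError(f"cap {label!r} references non-surface triangles")


@dataclass
class CenterlineSet:
    """Ordered branch polylines (cm) with unique labels.

    ``radii`` optionally carries per-point maximal inscribed radii (cm).
    """

    branches: dict[str, np.ndarray]                 # label -> (n, 3) cm
    radii: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for label, pts in self.branches.items():
            pts = np.asarray(pts, dtype=float).reshape(-1, 3)
            if len(pts) < 3:
                raise ValueError(f"centerline {label!r} has fewer than 3 points")
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(seg == 0):
                raise ValueError(f"centerline {label!r} has duplicate consecutive points")
            cleaned[label] = pts
        self.branches = cleaned

    @property
    def labels(self) -> list[str]:
        return list(self.branches)

    def points(self, label: str) -> np.ndarray:
        return self.branches[label]

    def arc_length(self, label: str) -> np.ndarray:
        """Cumulative arc length per point (cm), starting at 0."""
        pts = self.branches[label]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def total_length(self, label: str) -> float:
        return float(self.arc_length(label)[-1])

    def point_at_fraction(self, label: str, fraction: float) -> np.ndarray:
        """Interpolated point at a fraction of total arc length."""
        s = self.arc_length(label)
        target = fraction * s[-1]
        pts = self.branches[label]
        return np.array([np.interp(target, s, pts[:, i]) for i in range(3)])


@dataclass
class SubjectRecord:
    """One subject at one timepoint: demographics, catheter pressures, RV volumes."""

    id: str
    timepoint: str = "pre"              # pre / post
    sex: Optional[str] = None           # 'F' or 'M'
    age: Optional[float] = None         # years
    height: Optional[float] = None      # cm
    weight: Optional[float] = None      # kg
    spap: Optional[float] = None        # mmHg
    dpap: Optional[float] = None        # mmHg
    mpap: Optional[float] = None        # mmHg
    tpr: Optional[float] = None         # Wood units
    rvef: Optional[float] = None        # %
    rvedv: Optional[float] = None       # ml
    rvesv: Optional[float] = None       # ml
    rvsv: Optional[float] = None        # ml
    t_ed: Optional[float] = None        # s
    t_es: Optional[float] = None        # s

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spap is not None and self.dpap is not None and self.spap <= self.dpap:
            raise ValueError("SPAP must exceed DPAP")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


METRICS_COLUMNS = [
    "subject", "timepoint", "branch", "metric", "window", "statistic",
    "value", "units",
]
KEY_COLUMNS = METRICS_COLUMNS[:6]


class MetricsTable:
    """Long-format table of per-branch, per-window metric values.

    One row per (subject, timepoint, branch, metric, window, statistic); the
    key must be unique and every row carries a units string.
    """

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=METRICS_COLUMNS)
        missing = set(METRICS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"metrics table missing columns: {sorted(missing)}")
        self.df = df[METRICS_COLUMNS + [c for c in df.columns if c not in METRICS_COLUMNS]]
        self.validate()

    def validate(self) -> None:
        if len(self.df):
            if self.df.duplicated(subset=KEY_COLUMNS).any():
                dup = self.df[self.df.duplicated(subset=KEY_COLUMNS, keep=False)]
                raise ValueError(f"duplicate metric keys:\n{dup[KEY_COLUMNS]}")
            if (self.df["units"].astype(str).str.len() == 0).any():
                raise ValueError("every metric row needs a units string")

    def add(self, subject, timepoint, branch, metric, window, statistic,
            value, units) -> None:
        row = pd.DataFrame([{
            "subject": subject, "timepoint": timepoint, "branch": branch,
            "metric": metric, "window": window, "statistic": statistic,
            "value": value, "units": units,
        }])
        self.df = pd.concat([self.df, row], ignore_index=True) if len(self.df) else row
        self.validate()

    def get(self, **keys) -> float:
        mask = np.ones(len(self.df), dtype=bool)
        for k, v in keys.items():
            mask &= (self.df[k] == v).to_numpy()
        sel = self.df[mask]
        if len(sel) != 1:
            raise KeyError(f"{len(sel)} rows match {keys}")
        return float(sel["value"].iloc[0])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetricsTable):
            return NotImplemented
        a = self.df[METRICS_COLUMNS].reset_index(drop=True)
        b = other.df[METRICS_COLUMNS].reset_index(drop=True)
        return a.equals(b)


@dataclass
class Waveform:
    """Scalar time series over one cardiac cycle (flow, area, volume, ...)."""

    times: np.ndarray
    values: np.ndarray
    label: str
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 4:
            raise ValueError("waveform needs at least 4 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("waveform times must be strictly increasing")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


@dataclass
class CardiacWindows:
    """Systole is the half-open interval [t_ED, t_ES); diastole the complement."""

    t_ed: float
    t_es: float
    period: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_ed < self.t_es < self.period):
            raise ValueError("need 0 <= t_ED < t_ES < period")

    @property
    def t_systole(self) -> float:
        return self.t_es - self.t_ed

    def in_systole(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.t_ed) & (t < self.t_es)


@dataclass(frozen=True)
class FluidConstants:
    """Blood properties used for the Dean number."""

    density: float = 1.06    # g/cm^3
    viscosity: float = 0.04  # Poise = g/(cm s)


# Normalisation constants for percent-predicted RV metrics:
# predicted = m_sex * Age^a * Ht^b * Wt^c  (age years, height cm, weight kg).
PREDICTED_RV_CONSTANTS: dict[str, dict[str, float]] = {
    "RVEF":  {"a": 0.0706, "b": -0.00771, "c": -0.0782, "m_female": 75.19, "m_male": 71.52},
    "RVEDV": {"a": -0.258, "b": 1.582, "c": 0.382, "m_female": 27.94, "m_male": 31.50},
    "RVESV": {"a": -0.417, "b": 1.501, "c": 0.617, "m_female": 5.58, "m_male": 7.24},
    "RVSV":  {"a": -0.187, "b": 1.574, "c": 0.304, "m_female": 21.12, "m_male": 22.42},
}
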