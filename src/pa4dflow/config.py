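"""Run configuration with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .containers import FluidConstants


@dataclass
class RunConfig:
    """All tunable pipeline parameters.

    Defaults follow the standard protocol: proximal/mid slices at 10% and
    50% of the branch arc length, a central core of 30% of the slice
    radius for centerline velocity, 1.2 mm tetrahedral element targets,
    a 20% conservation-of-flow QC threshold and a 30 cm/s low-speed
    threshold for vortex candidate regions.
    """

    slice_fractions: tuple[float, float] = (0.10, 0.50)
    center_fraction: float = 0.30
    element_size: float = 0.12           # cm
    vorticity_mode: str = "vector-mean"  # default reported column
    hfi_floor: float = 1e-6              # cm/s * 1/s
    conservation_threshold: float = 0.20
    vortex_speed_threshold: float = 30.0  # cm/s
    fluid: FluidConstants = field(default_factory=FluidConstants)
    windows_source: str = "auto"         # 'record' | 'auto'
    upstroke_fraction: float = 0.10
    time_mode: str = "nearest"           # 'nearest' | 'linear'
    fill: str = "error"                  # 'error' | 'zero'
    smooth_window: int = 5               # centerline smoothing (points)
    bifurcation_radius: float | None = None  # cm; None -> inscribed radii
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.slice_fractions:
            if not 0 < f < 1:
                raise ValueError("slice fractions must lie in (0, 1)")
        for name in ("center_fraction", "element_size",
                     "conservation_threshold", "vortex_speed_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["slice_fractions"] = list(d["slice_fractions"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "fluid" in d and isinstance(d["fluid"], dict):
            d["fluid"] = FluidConstants(**d["fluid"])
        if "slice_fractions" in d:
            d["slice_fractions"] = tuple(d["slice_fractions"])
        return cls(**d)
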