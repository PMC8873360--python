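"""Run configuration for the grain pipeline.

The defaults target the structured-light regime the package emulates:
~0.17 mm point spacing and 0.05 mm single-sided surface noise. Only the
plane-distance threshold and the region-growing cluster bounds typically
need adjusting for other scenes.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # preprocessing
    voxel_leaf_mm: float = 0.15          # just under the scanner's native point distance
    outlier_k: int = 50
    outlier_std_mult: float = 1.0
    # stage-plane fit
    plane_dist_mm: float = 0.2
    ransac_iters: int = 200
    ransac_seed: int = 0
    plane_margin_mm: float = 0.5         # clearance above the stage kept as grain points
    # region growing
    rg_normal_angle_deg: float = 35.0    # see docs/methods.md for the curvature-radius argument
    rg_curvature_max: float = 0.08
    rg_min_points: int = 200
    rg_max_points: int = 200_000
    rg_neighbors: int = 30
    # meshing / traits
    mesh_search_radius_mm: float = 2.0
    mesh_mu: float = 2.5
    mesh_max_angle_deg: float = 120.0
    normal_k: int = 30
    # extents come from quadratic cap fits over a band of this many estimated
    # noise sd below each raw extreme (regression beats a raw max, which
    # rides the largest noise excursion); surface integrals use a heavy
    # resampling leaf instead, since their tilt bias scales like (sd/leaf)^2
    extent_band_sigma_mult: float = 6.0
    trait_leaf_factor: float = 6.0       # meshing/projection resampling leaf
    projection_alpha_mult: float = 3.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "ransac_seed":  # seeds may be 0
                continue
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v}")
        if self.rg_min_points >= self.rg_max_points:
            raise ValueError("rg_min_points must be < rg_max_points")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_config(path) -> RunConfig:
    """Load a flat key-value config (JSON or YAML).

    Unknown keys warn and are ignored; missing keys take the defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config must be a flat mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    return RunConfig(**{k: v for k, v in data.items() if k in known})
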