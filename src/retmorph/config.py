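"""Run configuration: every tunable default of the pipeline in one place.

Defaults are echoed into run manifests so every reported number can be
reproduced from the inputs alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # measurement annulus, in disc diameters outward from the disc EDGE
    annulus_inner_dd: float = 0.5
    annulus_outer_dd: float = 2.0
    annulus_all_branch_metrics: bool = True  # restrict BEA/BEC too, not only BA/BC

    # spur pruning
    spur_min_length: float | None = None  # None → adaptive threshold
    spur_length_floor: float = 5.0
    spur_diameter_factor: float = 1.5

    # rooting
    max_root_distance_dd: float = 3.0

    # daughter-direction fit for branch angles
    daughter_fit_factor: float = 3.0   # fit window, × parent diameter
    daughter_skip_factor: float = 1.0  # skipped near the junction, × parent diameter

    # main angle
    ma_vertex: str = "disc_center"  # or "custom"; override point below
    ma_vertex_point: tuple[float, float] | None = None
    ma_root_distance_dd: float = 1.0  # a tree counts as disc-rooted within this

    # statistics
    posthoc: str = "lsd"  # lsd | bonferroni | welch
    ci_level: float = 0.95

    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if not self.annulus_inner_dd < self.annulus_outer_dd:
            raise ValueError("annulus inner bound must be below the outer bound")
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must lie in (0, 1)")
        if self.posthoc not in ("lsd", "bonferroni", "welch"):
            raise ValueError(f"unknown post hoc method {self.posthoc!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ma_vertex_point" in data and data["ma_vertex_point"] is not None:
            data["ma_vertex_point"] = tuple(data["ma_vertex_point"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["ma_vertex_point"] is not None:
            d["ma_vertex_point"] = list(d["ma_vertex_point"])
        return d
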