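"""Pipeline configuration.

All tunable thresholds of the analysis live here with their clinical
defaults: the burr length (6 px), the centerline line-fit window (N=5),
the parent/child attachment distance (d_n = 10 px city-block), the
inter-frame matching thresholds (d_s, d_e < 65 px, length ratio > 0.80),
the diameter-curve smoothing window, the stenosis reporting floor (30 %),
and the myocardial-bridge rules (stenosis swing >= 0.25 or diameter ratio
<= 0.75, extrema at least 3 frames apart).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and window lengths for the whole analysis chain.

    Units are pixels and frames throughout; ``rate_min`` and the bridge
    thresholds are dimensionless fractions.
    """

    #: skeleton branches shorter than this many own pixels are burrs
    burr_min_len: int = 6
    #: number of centerline pixels in the local least-squares line fit
    line_fit_N: int = 5
    #: max city-block distance between a parent end and a child start
    d_n_threshold: float = 10.0
    #: inter-frame match: max city-block distance between start points
    d_s_max: float = 65.0
    #: inter-frame match: max city-block distance between end points
    d_e_max: float = 65.0
    #: inter-frame match: min length ratio min(L1,L2)/max(L1,L2)
    rate_min: float = 0.80
    #: moving-average window for diameter-curve smoothing (odd)
    smooth_N_w: int = 5
    #: stenosis findings below this percent are reported as normal
    stenosis_report_floor: float = 30.0
    #: bridge rule A: min swing of stenosis degree (fraction) over a track
    bridge_stenosis_delta: float = 0.25
    #: bridge rule B: max ratio min/max of per-frame mean diameter
    bridge_diameter_ratio: float = 0.75
    #: min frame separation of the extrema for either bridge rule
    bridge_frame_gap: int = 3
    #: centerline samples closer than this to a junction are not profiled
    junction_exclusion: float = 2.0
    #: max marching distance per side when probing the vessel edge
    normal_search_cap: float = 50.0
    #: fraction of a peripheral (leaf) vessel's distal end excluded from
    #: stenosis candidates
    peripheral_distal_exclusion: float = 0.20

    def __post_init__(self) -> None:
        for name in (
            "burr_min_len", "line_fit_N", "d_n_threshold", "d_s_max",
            "d_e_max", "smooth_N_w", "bridge_stenosis_delta",
            "bridge_diameter_ratio", "bridge_frame_gap",
            "normal_search_cap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineConfig.{name} must be positive")
        if not (0.0 < self.rate_min < 1.0):
            raise ValueError("PipelineConfig.rate_min must be in (0, 1)")
        if self.smooth_N_w % 2 == 0:
            raise ValueError("PipelineConfig.smooth_N_w must be odd")
        if self.junction_exclusion < 0:
            raise ValueError("PipelineConfig.junction_exclusion must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
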