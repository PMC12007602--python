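"""Analysis configuration shared by every pipeline stage.

The defaults encode the study protocol: 1000 Hz epochs of (-200, 700) ms,
20-ms post-onset bins, a >=4-consecutive-significant-bins responsiveness
rule at alpha = 0.05, a 1-cm geodesic disk with a logistic distance kernel
(midpoint 7.5 mm, steepness 2 per mm), seven mesh nodes per lead, 10 %
display thresholds, the >=10 %-on->=4-leads regional selection rule and a
0.5 connectivity-probability cut.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    bin_ms: int = 20
    min_consecutive_bins: int = 4
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    analysis_window: tuple[float, float] = (0.0, 700.0)
    n_time_bins: int = 35
    map_radius_mm: float = 10.0
    kernel_midpoint_mm: float = 7.5
    kernel_steepness: float = 2.0  # per mm
    nodes_per_lead: int = 7
    map_threshold_pct: float = 10.0
    region_min_pct: float = 10.0
    region_min_leads: int = 4
    conn_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.min_consecutive_bins < 1:
            raise ValueError("min_consecutive_bins must be >= 1")
        if not self.baseline_window[0] < self.baseline_window[1] <= 0:
            raise ValueError(
                "baseline_window must end at or before stimulus onset"
            )
        if not 0 <= self.analysis_window[0] < self.analysis_window[1]:
            raise ValueError("analysis_window must start at or after onset")
        span = self.analysis_window[1] - self.analysis_window[0]
        if self.n_time_bins * self.bin_ms != span:
            raise ValueError(
                f"n_time_bins*bin_ms ({self.n_time_bins * self.bin_ms}) must "
                f"equal the analysis window length ({span})"
            )
        if self.map_radius_mm <= 0 or self.kernel_midpoint_mm <= 0:
            raise ValueError("kernel geometry must be positive")
        if self.nodes_per_lead < 1:
            raise ValueError("nodes_per_lead must be >= 1")
        for name in ("map_threshold_pct", "region_min_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if not 0 <= self.conn_threshold <= 1:
            raise ValueError("conn_threshold must lie in [0, 1]")

    # -- serialisation -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("baseline_window", "analysis_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


DEFAULT_CONFIG = AnalysisConfig()
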