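"""End-to-end orchestration: epochs in, per-lead result table out."""

from __future__ import annotations

import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .datatypes import EMOTIONAL_CONDITIONS, EpochedRecording
from .stats import ResponsivenessDetector, SelectivityTester


def analyze_recording(
    recording: EpochedRecording,
    config: AnalysisConfig = DEFAULT_CONFIG,
    contrasts: tuple[str, ...] = (
        "smiling_vs_neutral",
        "fearful_vs_neutral",
    ),
    method: str = "paired",
) -> pd.DataFrame:
    """Responsiveness then gated selectivity for every lead.

    Returns one row per lead with per-condition responsiveness, and per
    contrast the selectivity flag, ANOVA p-values and (for selective
    leads) the peak latency and its 100-ms class. Selectivity is only
    evaluated on leads responsive in at least one emotional condition,
    so selective leads are by construction a subset of responsive ones.
    """
    detector = ResponsivenessDetector(config=config, method=method).fit(
        recording
    )
    tester = SelectivityTester(config=config, contrasts=contrasts).fit(
        recording, gate=detector.responsive_any_
    )
    rows = []
    for lead_id in recording.lead_ids:
        row: dict = {"lead_id": lead_id}
        for condition in EMOTIONAL_CONDITIONS:
            row[f"responsive_{condition}"] = bool(
                detector.responsive_.loc[lead_id, condition]
            )
        row["responsive"] = bool(detector.responsive_any_[lead_id])
        for contrast in contrasts:
            res = tester.results_.get((lead_id, contrast))
            row[f"selective_{contrast}"] = (
                bool(res.selective) if res else False
            )
            row[f"p_interaction_{contrast}"] = (
                res.p_interaction if res else float("nan")
            )
            row[f"peak_latency_ms_{contrast}"] = (
                res.peak_latency_ms if res else None
            )
            row[f"peak_class_ms_{contrast}"] = (
                res.peak_class_ms if res else None
            )
        row["selective"] = any(
            row[f"selective_{c}"] for c in contrasts
        )
        rows.append(row)
    return pd.DataFrame(rows)
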