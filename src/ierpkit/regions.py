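"""Parcellation-level summaries of lead statistics.

Leads inherit the majority region among their 7 assigned mesh nodes;
per (region, hemisphere) the fraction of significant leads is tabulated
and a region is *selected* for downstream connectivity study only when
significant leads are at least 10 % of its recorded leads AND at least
four leads — the second clause guards sparsely sampled parcels.
Hemispheric asymmetry is tested with a 2x2 chi-squared (Yates correction
off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .config import DEFAULT_CONFIG, AnalysisConfig
from .datatypes import CorticalMesh, LeadSet, Parcellation


@dataclass
class RegionalSummary:
    region: str
    hemisphere: str
    n_leads: int
    n_significant: int
    percent: float
    selected: bool


@dataclass
class LateralizationTest:
    region: str
    contingency: np.ndarray  # 2x2: hemisphere x (significant, not)
    chi2: float
    p: float


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (display convention)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def assign_regions(
    leads: LeadSet,
    mesh: CorticalMesh,
    parcellation: Parcellation,
    assignment: dict[str, np.ndarray],
) -> LeadSet:
    """Label each lead by the majority region among its assigned nodes.

    Ties are broken by the region of the node nearest the lead position;
    leads whose nodes carry no label keep ``region_label=None`` and are
    dropped from regional summaries.
    """
    labels: dict[str, str | None] = {}
    for lead in leads:
        nodes = np.asarray(assignment.get(lead.lead_id, []), dtype=int)
        node_regions = [
            str(parcellation.node_labels[n])
            for n in nodes
            if parcellation.node_labels[n]
        ]
        if not node_regions:
            labels[lead.lead_id] = None
            continue
        counts = pd.Series(node_regions).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) == 1:
            labels[lead.lead_id] = top[0]
        else:
            # tie: walk nodes in order of distance to the lead
            order = np.argsort(
                np.linalg.norm(
                    mesh.node_positions[nodes] - lead.position, axis=1
                ),
                kind="stable",
            )
            labels[lead.lead_id] = next(
                str(parcellation.node_labels[n])
                for n in nodes[order]
                if str(parcellation.node_labels[n]) in top
            )
    return leads.with_regions(labels)


def regional_summary(
    leads: LeadSet,
    significant: dict[str, bool] | pd.Series,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per (region, hemisphere) significant-lead counts and selection flag.

    ``significant`` must cover every region-labelled lead. ``percent`` is
    exact; ``percent_display`` applies the half-away-from-zero integer
    rounding used in printed tables.
    """
    rows = []
    for lead in leads:
        if lead.region_label is None:
            continue
        if lead.lead_id not in significant:
            raise ValueError(
                f"no significance flag for labelled lead {lead.lead_id!r}"
            )
        rows.append(
            {
                "region": lead.region_label,
                "hemisphere": lead.hemisphere,
                "significant": bool(significant[lead.lead_id]),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "region",
                "hemisphere",
                "n_leads",
                "n_significant",
                "percent",
                "percent_display",
                "selected",
            ]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["region", "hemisphere"], sort=True)
        .agg(
            n_leads=("significant", "size"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    out["percent"] = 100.0 * out["n_significant"] / out["n_leads"]
    out["percent_display"] = out["percent"].map(round_half_away)
    out["selected"] = (out["percent"] >= config.region_min_pct) & (
        out["n_significant"] >= config.region_min_leads
    )
    return out


def summarize_counts(
    n_significant: int,
    n_leads: int,
    region: str = "",
    hemisphere: str = "L",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> RegionalSummary:
    """Selection rule applied directly to printed count pairs."""
    if not 0 <= n_significant <= n_leads:
        raise ValueError("need 0 <= n_significant <= n_leads")
    percent = 100.0 * n_significant / n_leads if n_leads else 0.0
    return RegionalSummary(
        region=region,
        hemisphere=hemisphere,
        n_leads=n_leads,
        n_significant=n_significant,
        percent=percent,
        selected=percent >= config.region_min_pct
        and n_significant >= config.region_min_leads,
    )


def chi2_lateralization(
    left: tuple[int, int],
    right: tuple[int, int],
    correction: bool = False,
    region: str = "",
) -> LateralizationTest:
    """Chi-squared test of hemisphere x significant/non-significant counts.

    ``left`` and ``right`` are (significant, total) pairs. Raises when any
    expected cell is zero (an exact test is then the right tool).
    """
    table = []
    for sig, total in (left, right):
        if not 0 <= sig <= total or total <= 0:
            raise ValueError("need totals >= significant >= 0, totals > 0")
        table.append([sig, total - sig])
    table = np.array(table, dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        raise ValueError(
            "a zero expected cell makes chi-squared invalid; "
            "use an exact test"
        )
    res = chi2_contingency(table, correction=correction)
    return LateralizationTest(
        region=region,
        contingency=table,
        chi2=float(res.statistic),
        p=float(res.pvalue),
    )
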