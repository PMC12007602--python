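"""Tabulation of high-frequency stimulation outcomes.

Clinical mapping sessions label each stimulated site with one of six
outcome categories (sensorimotor, interoceptive, emotional, language,
unspecific subjective, unresponsive); sensorimotor effects additionally
carry the affected body district. This module validates raw rows into
records and produces left/right/total count tables plus the headline
percentage of unresponsive sites, derived as stimulated minus responsive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import (
    BODY_DISTRICTS,
    STIMULATION_CATEGORIES,
    StimulationRecord,
)


@dataclass
class StimulationSummary:
    by_category: pd.DataFrame  # index category, columns L, R, total
    by_district: pd.DataFrame  # sensorimotor only; index district
    n_stimulated: int
    n_responsive: int
    percent_unresponsive: float
    percent_unresponsive_display: int


def categorize(rows: list[dict]) -> list[StimulationRecord]:
    """Validate raw table rows into records.

    Category strings are case-insensitive; a body district is required
    for sensorimotor outcomes and forbidden elsewhere.
    """
    records = []
    for i, row in enumerate(rows):
        category = str(row.get("category", "")).strip().lower()
        if category not in STIMULATION_CATEGORIES:
            raise ValueError(
                f"row {i + 1}: unknown category {row.get('category')!r}; "
                f"expected one of {STIMULATION_CATEGORIES}"
            )
        district = row.get("body_district")
        if district is not None:
            district = str(district).strip().lower()
            if district in ("", "nan", "none"):
                district = None
            elif district not in BODY_DISTRICTS:
                raise ValueError(
                    f"row {i + 1}: unknown body district "
                    f"{row.get('body_district')!r}; "
                    f"expected one of {BODY_DISTRICTS}"
                )
        records.append(
            StimulationRecord(
                site_id=str(row.get("site_id", f"site{i + 1}")),
                hemisphere=str(row.get("hemisphere", "")).strip().upper(),
                current_ma=float(row.get("current_ma", 0.0)),
                category=category,
                body_district=district,
            )
        )
    return records


def tabulate(records: list[StimulationRecord]) -> StimulationSummary:
    """Count outcomes by category (and body district for sensorimotor)."""
    cat_counts = {
        c: {"L": 0, "R": 0} for c in STIMULATION_CATEGORIES
    }
    district_counts = {
        d: {"L": 0, "R": 0} for d in BODY_DISTRICTS if d != "none"
    }
    for rec in records:
        cat_counts[rec.category][rec.hemisphere] += 1
        if (
            rec.category == "sensorimotor"
            and rec.body_district in district_counts
        ):
            district_counts[rec.body_district][rec.hemisphere] += 1
    by_category = pd.DataFrame(cat_counts).T
    by_category["total"] = by_category["L"] + by_category["R"]
    by_category.index.name = "category"
    by_district = pd.DataFrame(district_counts).T
    by_district["total"] = by_district["L"] + by_district["R"]
    by_district.index.name = "body_district"
    n_stimulated = len(records)
    n_responsive = n_stimulated - int(
        by_category.loc["unresponsive", "total"]
    )
    pct = (
        100.0 * (n_stimulated - n_responsive) / n_stimulated
        if n_stimulated
        else 0.0
    )
    return StimulationSummary(
        by_category=by_category,
        by_district=by_district,
        n_stimulated=n_stimulated,
        n_responsive=n_responsive,
        percent_unresponsive=pct,
        percent_unresponsive_display=int(round(pct)),
    )


def unresponsive_percent(n_stimulated: int, n_responsive: int) -> float:
    """Headline unresponsive percentage from printed totals."""
    if not 0 <= n_responsive <= n_stimulated or n_stimulated == 0:
        raise ValueError("need 0 <= responsive <= stimulated, stimulated > 0")
    return 100.0 * (n_stimulated - n_responsive) / n_stimulated
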