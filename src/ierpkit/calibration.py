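"""Monte-Carlo calibration experiments for the statistical chain.

These run the pipeline on its own synthetic generators to measure
operating characteristics: the false-positive rate of the run-length
responsiveness rule under pure noise (against the exact enumeration
rate), detection/selectivity power and peak-class recovery for planted
responses, and planted-partition recovery of the connectivity clustering.
"""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .connectivity import RegionClusterer, compare_directions, same_partition
from .datatypes import Lead, LeadSet
from .simulate import EvokedSpec, NoiseSpec, simulate_connectivity, simulate_epochs
from .stats import (
    consecutive_run_null_rate,
    detect_responsive,
    test_selectivity,
)


def _subseed(seed: int, i: int) -> int:
    return int((seed * 1000003 + i) % (2**31 - 1))


def _free_leads(n: int) -> LeadSet:
    return LeadSet(
        [Lead(f"L{i:04d}", np.array([float(i), 0.0, 0.0]), "L") for i in range(n)]
    )


def null_responsiveness_calibration(
    n_leads: int = 2000,
    n_trials: int = 54,
    seed: int = 0,
    batch_size: int = 100,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """False-positive rate of the >=4-consecutive-bins rule on white noise.

    Simulates ``n_leads`` leads with no evoked component, runs the
    responsiveness detector on the smiling trials of each, and compares
    the flag rate to the exact iid run-length rate.
    """
    flagged = 0
    done = 0
    b = 0
    while done < n_leads:
        n = min(batch_size, n_leads - done)
        leads = _free_leads(n)
        rec = simulate_epochs(
            leads,
            {},
            NoiseSpec(white_sd=1.0),
            n_trials_per_condition=n_trials,
            config=config,
            seed=_subseed(seed, b),
        )
        for lead_id in rec.lead_ids:
            flagged += detect_responsive(
                rec, lead_id, "smiling", config
            ).responsive
        done += n
        b += 1
    expected = consecutive_run_null_rate(
        config.n_time_bins, config.alpha, config.min_consecutive_bins
    )
    return {
        "n_leads": n_leads,
        "observed_rate": flagged / n_leads,
        "expected_rate": expected,
        "n_flagged": flagged,
    }


def planted_recovery(
    n_seeds: int = 100,
    amplitude: float = 5.0,
    white_sd: float = 1.0,
    n_trials: int = 54,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """Power and peak-class recovery for planted evoked responses.

    Each replicate plants the same bump (amplitude x noise SD, latency
    cycling through 100..500 ms) in the smiling and fearful conditions of
    one lead and checks responsiveness, smiling-vs-neutral selectivity and
    the recovered peak-latency class.
    """
    latencies = (100.0, 200.0, 300.0, 400.0, 500.0)
    n_resp = n_sel = n_class = 0
    for i in range(n_seeds):
        latency = latencies[i % len(latencies)]
        leads = _free_leads(1)
        evoked = {
            "L0000": {
                c: EvokedSpec(c, amplitude * white_sd, latency)
                for c in ("smiling", "fearful")
            }
        }
        rec = simulate_epochs(
            leads,
            evoked,
            NoiseSpec(white_sd=white_sd),
            n_trials_per_condition=n_trials,
            config=config,
            seed=_subseed(seed, i),
        )
        responsive = detect_responsive(
            rec, "L0000", "smiling", config
        ).responsive
        n_resp += responsive
        if responsive:
            res = test_selectivity(rec, "L0000", "smiling_vs_neutral", config)
            n_sel += res.selective
            if res.selective and res.peak_class_ms == latency:
                n_class += 1
    return {
        "n_seeds": n_seeds,
        "responsive_rate": n_resp / n_seeds,
        "selective_rate": n_sel / n_seeds,
        "class_recovery_rate": n_class / n_seeds,
    }


FIG5_LIKE_REGIONS = (
    "vmPFC",
    "rACC",
    "cACC",
    "LatOFC1",
    "LatOFC2",
    "IFGtri",
    "AI",
    "RO",
    "IFJ",
)
FIG5_LIKE_BLOCKS = (
    ("vmPFC", "rACC", "cACC"),  # cingulate
    ("LatOFC1", "LatOFC2"),  # orbitofrontal
    ("IFGtri", "AI"),  # lateral prefrontal
    ("RO", "IFJ"),  # premotor
)


def connectivity_recovery(
    n_seeds: int = 100,
    p_within: float = 0.8,
    p_between: float = 0.1,
    noise_sd: float = 0.02,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict:
    """Planted 4-block recovery and afferent/efferent partition agreement.

    Uses a 9-region, 4-block structure shaped like the frontal/insular
    ROI set (cingulate, orbitofrontal, lateral prefrontal, premotor).
    """
    regions = list(FIG5_LIKE_REGIONS)
    blocks = [list(b) for b in FIG5_LIKE_BLOCKS]
    membership = {r: k for k, block in enumerate(blocks) for r in block}
    truth = np.array([membership[r] for r in regions])
    n_rec = n_same = 0
    for i in range(n_seeds):
        aff = simulate_connectivity(
            regions, blocks, p_within, p_between, noise_sd,
            seed=_subseed(seed, 2 * i), direction="afferent",
        )
        eff = simulate_connectivity(
            regions, blocks, p_within, p_between, noise_sd,
            seed=_subseed(seed, 2 * i + 1), direction="efferent",
        )
        labels = RegionClusterer(n_clusters=4, config=config).fit_predict(aff)
        n_rec += same_partition(labels, truth)
        n_same += compare_directions(aff, eff, config).same_partition_k4
    return {
        "n_seeds": n_seeds,
        "recovery_rate": n_rec / n_seeds,
        "direction_agreement_rate": n_same / n_seeds,
    }
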