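"""Per-lead evoked-potential statistics.

The chain mirrors standard SEEG practice for passive-viewing paradigms:

1. iERP: per-trial subtractive baseline correction against the prestimulus
   interval, then a trial average per condition.
2. Responsiveness: the post-onset window is cut into 20-ms bins; each bin's
   per-trial mean is tested against that trial's baseline mean (paired
   t-test, two-sided, alpha = 0.05) and a lead is responsive only when at
   least four consecutive bins are significant — a run-length rule that
   suppresses the per-bin false-positive rate by orders of magnitude.
3. Selectivity: a two-way mixed ANOVA per emotional-vs-neutral contrast,
   Condition between trials and Time (the 35 bins) within trials; a lead is
   selective when the interaction and at least one main effect are
   significant, and planned per-bin contrasts (uncorrected t-tests) then
   localise the difference.
4. Peak latency: the argmax of |iERP| after onset, classed into the
   100/200/300/400/500-ms families with half-open [c-50, c+50) bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, AnalysisConfig
from .datatypes import EMOTIONAL_CONDITIONS, EpochedRecording

CONTRASTS = {
    "smiling_vs_neutral": ("smiling", "neutral"),
    "fearful_vs_neutral": ("fearful", "neutral"),
    "smiling_vs_fearful": ("smiling", "fearful"),
}

PEAK_CLASSES_MS = (100, 200, 300, 400, 500)


@dataclass
class IERP:
    """Trial-averaged, baseline-corrected evoked waveform at one lead."""

    lead_id: str
    condition: str
    waveform: np.ndarray
    times_ms: np.ndarray
    n_trials: int


@dataclass
class ResponsivenessResult:
    lead_id: str
    condition: str
    bin_p_values: np.ndarray
    significant_bins: np.ndarray
    responsive: bool
    max_run_length: int


@dataclass
class SelectivityResult:
    lead_id: str
    contrast: str
    p_interaction: float
    p_main_condition: float
    p_main_time: float
    selective: bool
    posthoc_bins: np.ndarray | None
    peak_latency_ms: float | None
    peak_class_ms: int | None


# ---------------------------------------------------------------------------
# sample bookkeeping
# ---------------------------------------------------------------------------


def _sample_index(recording: EpochedRecording, t_ms: float) -> int:
    start = recording.epoch_window[0]
    return round((t_ms - start) * recording.sampling_rate / 1000.0)


def baseline_slice(
    recording: EpochedRecording, config: AnalysisConfig
) -> slice:
    return slice(
        _sample_index(recording, config.baseline_window[0]),
        _sample_index(recording, config.baseline_window[1]),
    )


def bin_slices(
    recording: EpochedRecording, config: AnalysisConfig
) -> tuple[int, int]:
    """(first analysis sample, samples per bin) for the post-onset bins."""
    first = _sample_index(recording, config.analysis_window[0])
    per_bin = round(config.bin_ms * recording.sampling_rate / 1000.0)
    if per_bin < 1:
        raise ValueError("bin shorter than one sample")
    needed = first + config.n_time_bins * per_bin
    if needed > recording.n_samples:
        raise ValueError(
            f"epoch too short: bins need {needed} samples, "
            f"recording has {recording.n_samples}"
        )
    return first, per_bin


def baseline_correct(
    trials: np.ndarray, recording: EpochedRecording, config: AnalysisConfig
) -> np.ndarray:
    """Subtract each trial's prestimulus mean. Idempotent up to rounding."""
    base = trials[..., baseline_slice(recording, config)].mean(axis=-1)
    return trials - base[..., None]


def trial_bin_means(
    trials: np.ndarray, recording: EpochedRecording, config: AnalysisConfig
) -> np.ndarray:
    """Per-trial means over the post-onset 20-ms bins -> (trials, n_bins)."""
    first, per_bin = bin_slices(recording, config)
    window = trials[..., first : first + config.n_time_bins * per_bin]
    shape = window.shape[:-1] + (config.n_time_bins, per_bin)
    return window.reshape(shape).mean(axis=-1)


# ---------------------------------------------------------------------------
# iERP
# ---------------------------------------------------------------------------


def compute_ierp(
    recording: EpochedRecording,
    lead_id: str,
    condition: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> IERP:
    trials = recording.trials(lead_id, condition)
    if len(trials) == 0:
        raise ValueError(
            f"lead {lead_id!r} has no {condition!r} trials"
        )
    corrected = baseline_correct(trials, recording, config)
    return IERP(
        lead_id=lead_id,
        condition=condition,
        waveform=corrected.mean(axis=0),
        times_ms=recording.times_ms,
        n_trials=len(trials),
    )


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------


def bin_baseline_pvalues(
    trials: np.ndarray,
    recording: EpochedRecording,
    config: AnalysisConfig = DEFAULT_CONFIG,
    method: str = "paired",
) -> np.ndarray:
    """Two-sided p-value per post-onset bin versus the prestimulus baseline.

    ``paired`` (default): one-sample t-test across trials on per-trial
    (bin mean - baseline mean) differences. ``pooled``: independent-sample
    t-test of the per-trial bin means against the per-trial baseline means.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    base = trials[:, baseline_slice(recording, config)].mean(axis=1)
    binm = trial_bin_means(trials, recording, config)
    if method == "paired":
        res = sps.ttest_1samp(binm - base[:, None], 0.0, axis=0)
    elif method == "pooled":
        res = sps.ttest_ind(binm, base[:, None], axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.asarray(res.pvalue)


def max_run_length(flags: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = run = 0
    for f in np.asarray(flags, dtype=bool):
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def detect_responsive(
    recording: EpochedRecording,
    lead_id: str,
    condition: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
    method: str = "paired",
) -> ResponsivenessResult:
    trials = recording.trials(lead_id, condition)
    if len(trials) < 2:
        raise ValueError(
            f"lead {lead_id!r}: need >= 2 {condition!r} trials"
        )
    p = bin_baseline_pvalues(trials, recording, config, method=method)
    significant = p < config.alpha
    run = max_run_length(significant)
    return ResponsivenessResult(
        lead_id=lead_id,
        condition=condition,
        bin_p_values=p,
        significant_bins=significant,
        responsive=run >= config.min_consecutive_bins,
        max_run_length=run,
    )


def consecutive_run_null_rate(
    n_bins: int = 35, p: float = 0.05, min_run: int = 4
) -> float:
    """Exact P(some run of >= min_run successes | n_bins iid Bernoulli(p)).

    Dynamic programme over the trailing-run length; this is the expected
    false-positive rate of the run-length responsiveness rule when the
    per-bin tests are independent with level ``p``.
    """
    if min_run < 1 or n_bins < 0 or not 0 <= p <= 1:
        raise ValueError("invalid run-length parameters")
    states = np.zeros(min_run)
    states[0] = 1.0
    absorbed = 0.0
    for _ in range(n_bins):
        new = np.zeros(min_run)
        new[0] = states.sum() * (1 - p)
        new[1:] = states[:-1] * p
        absorbed += states[min_run - 1] * p
        states = new
    return float(absorbed)


# ---------------------------------------------------------------------------
# selectivity (mixed two-way ANOVA: Condition between trials, Time within)
# ---------------------------------------------------------------------------


def mixed_anova_pvalues(
    group_a: np.ndarray,
    group_b: np.ndarray,
    sphericity_correction: bool = False,
) -> tuple[float, float, float]:
    """(p_condition, p_time, p_interaction) for two trials x bins groups.

    Split-plot design: trials are the random unit nested in Condition;
    Time is the repeated factor. Degenerate zero-variance designs yield
    p = 1 for the vanished effects.
    """
    import pingouin as pg

    n_a, n_bins = group_a.shape
    n_b = group_b.shape[0]
    if group_b.shape[1] != n_bins:
        raise ValueError("unequal bin grids between conditions")
    values = np.concatenate([group_a, group_b], axis=0)
    trials = np.repeat(np.arange(n_a + n_b), n_bins)
    cond = np.repeat(
        np.array(["a"] * n_a + ["b"] * n_b, dtype=object), n_bins
    )
    time = np.tile(np.arange(n_bins), n_a + n_b)
    df = pd.DataFrame(
        {
            "value": values.ravel(),
            "trial": trials,
            "condition": cond,
            "time": time,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.mixed_anova(
            data=df,
            dv="value",
            within="time",
            subject="trial",
            between="condition",
            correction=sphericity_correction,
        ).set_index("Source")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"

    def _p(source: str) -> float:
        p = float(aov.loc[source, p_col])
        return 1.0 if np.isnan(p) else p

    return _p("condition"), _p("time"), _p("Interaction")


def test_selectivity(
    recording: EpochedRecording,
    lead_id: str,
    contrast: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
    sphericity_correction: bool = False,
) -> SelectivityResult:
    """Mixed Condition x Time ANOVA for one emotional/neutral contrast.

    Selective requires a significant interaction plus at least one
    significant main effect; only then are planned per-bin contrasts and
    the peak latency of the first (emotional) condition's iERP computed.
    """
    if contrast not in CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of "
            f"{sorted(CONTRASTS)}"
        )
    cond_a, cond_b = CONTRASTS[contrast]
    trials_a = recording.trials(lead_id, cond_a)
    trials_b = recording.trials(lead_id, cond_b)
    if len(trials_a) < 2 or len(trials_b) < 2:
        raise ValueError(
            f"lead {lead_id!r}: need >= 2 trials per condition"
        )
    bins_a = trial_bin_means(
        baseline_correct(trials_a, recording, config), recording, config
    )
    bins_b = trial_bin_means(
        baseline_correct(trials_b, recording, config), recording, config
    )
    p_cond, p_time, p_inter = mixed_anova_pvalues(
        bins_a, bins_b, sphericity_correction
    )
    selective = p_inter < config.alpha and (
        p_cond < config.alpha or p_time < config.alpha
    )
    posthoc = peak = klass = None
    if selective:
        res = sps.ttest_ind(bins_a, bins_b, axis=0)
        posthoc = np.asarray(res.pvalue) < config.alpha
        ierp = compute_ierp(recording, lead_id, cond_a, config)
        peak, klass = peak_latency(ierp, config)
    return SelectivityResult(
        lead_id=lead_id,
        contrast=contrast,
        p_interaction=p_inter,
        p_main_condition=p_cond,
        p_main_time=p_time,
        selective=selective,
        posthoc_bins=posthoc,
        peak_latency_ms=peak,
        peak_class_ms=klass,
    )


# ---------------------------------------------------------------------------
# peak latency
# ---------------------------------------------------------------------------


def peak_latency(
    ierp: IERP, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[float, int]:
    """(latency ms, latency class ms) of the absolute iERP peak after onset.

    The peak is polarity-free (argmax of |waveform|, earliest sample wins
    ties) and classed into {100, ..., 500} with half-open [c-50, c+50)
    bins; latencies below 50 ms fall in the 100-ms class and those at or
    above 550 ms in the 500-ms class.
    """
    lo, hi = config.analysis_window
    mask = (ierp.times_ms > lo) & (ierp.times_ms <= hi)
    segment = np.abs(ierp.waveform[mask])
    if segment.size == 0 or np.ptp(ierp.waveform[mask]) == 0:
        raise ValueError(
            f"lead {ierp.lead_id!r}: waveform constant over the analysis "
            "window; peak latency undefined"
        )
    times = ierp.times_ms[mask]
    latency = float(times[np.argmax(segment)])
    klass = int(np.clip(np.floor((latency + 50) / 100), 1, 5)) * 100
    return latency, klass


# ---------------------------------------------------------------------------
# sklearn-style estimators over whole recordings
# ---------------------------------------------------------------------------


class ResponsivenessDetector(BaseEstimator):
    """Flag responsive leads across a recording.

    Fitted attributes: ``results_`` maps (lead_id, condition) to
    :class:`ResponsivenessResult`; ``responsive_`` is a leads x conditions
    boolean frame; ``responsive_any_`` flags leads responsive in at least
    one tested (emotional) condition — the gate for selectivity testing.
    """

    def __init__(
        self,
        config: AnalysisConfig = DEFAULT_CONFIG,
        conditions: tuple[str, ...] = EMOTIONAL_CONDITIONS,
        method: str = "paired",
    ):
        self.config = config
        self.conditions = conditions
        self.method = method

    def fit(self, recording: EpochedRecording, y=None):
        results = {}
        for lead_id in recording.lead_ids:
            for condition in self.conditions:
                results[(lead_id, condition)] = detect_responsive(
                    recording, lead_id, condition, self.config, self.method
                )
        self.results_ = results
        self.responsive_ = pd.DataFrame(
            {
                c: [
                    results[(l, c)].responsive for l in recording.lead_ids
                ]
                for c in self.conditions
            },
            index=pd.Index(recording.lead_ids, name="lead_id"),
        )
        self.responsive_any_ = self.responsive_.any(axis=1)
        return self

    def predict(self, recording: EpochedRecording | None = None):
        if recording is not None:
            self.fit(recording)
        return self.responsive_any_.to_numpy()


class SelectivityTester(BaseEstimator):
    """Run the emotional-vs-neutral contrasts on responsive leads only.

    ``gate`` maps lead_id -> bool (typically
    ``ResponsivenessDetector.responsive_any_``); ungated leads are skipped,
    enforcing that selective leads are a subset of responsive ones.
    """

    def __init__(
        self,
        config: AnalysisConfig = DEFAULT_CONFIG,
        contrasts: tuple[str, ...] = (
            "smiling_vs_neutral",
            "fearful_vs_neutral",
        ),
        sphericity_correction: bool = False,
    ):
        self.config = config
        self.contrasts = contrasts
        self.sphericity_correction = sphericity_correction

    def fit(
        self,
        recording: EpochedRecording,
        gate: pd.Series | dict | None = None,
    ):
        results = {}
        for lead_id in recording.lead_ids:
            if gate is not None and not bool(gate[lead_id]):
                continue
            for contrast in self.contrasts:
                results[(lead_id, contrast)] = test_selectivity(
                    recording,
                    lead_id,
                    contrast,
                    self.config,
                    self.sphericity_correction,
                )
        self.results_ = results
        rows = []
        for (lead_id, contrast), r in results.items():
            rows.append(
                {
                    "lead_id": lead_id,
                    "contrast": contrast,
                    "selective": r.selective,
                    "p_interaction": r.p_interaction,
                    "p_main_condition": r.p_main_condition,
                    "p_main_time": r.p_main_time,
                    "peak_latency_ms": r.peak_latency_ms,
                    "peak_class_ms": r.peak_class_ms,
                }
            )
        self.frame_ = pd.DataFrame(
            rows,
            columns=[
                "lead_id",
                "contrast",
                "selective",
                "p_interaction",
                "p_main_condition",
                "p_main_time",
                "peak_latency_ms",
                "peak_class_ms",
            ],
        )
        return self
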