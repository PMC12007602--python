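import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ierpkit as ik
from ierpkit.stats import (
    CONTRASTS,
    baseline_correct,
    bin_baseline_pvalues,
    max_run_length,
    mixed_anova_pvalues,
)

from conftest import make_recording


def recording_from_array(data, conditions):
    """Wrap a (leads, trials, 900) array in a standard epoch container."""
    data = np.asarray(data, dtype=float)
    return ik.EpochedRecording(
        lead_ids=[f"L{i:03d}" for i in range(data.shape[0])],
        conditions=np.array(conditions, dtype=object),
        data=data,
        sampling_rate=1000.0,
        epoch_window=(-200.0, 700.0),
    )


class TestIERP:
    def test_constant_trials_cancel_to_zero(self):
        data = np.full((1, 3, 900), 7.25)
        rec = recording_from_array(data, ["smiling"] * 3)
        ierp = ik.compute_ierp(rec, "L000", "smiling")
        np.testing.assert_allclose(ierp.waveform, 0.0, atol=1e-12)

    def test_single_trial_is_itself_minus_baseline(self):
        rng = np.random.default_rng(0)
        trial = rng.standard_normal(900)
        rec = recording_from_array(trial[None, None, :], ["neutral"])
        ierp = ik.compute_ierp(rec, "L000", "neutral")
        np.testing.assert_allclose(
            ierp.waveform, trial - trial[:200].mean(), atol=1e-12
        )

    def test_zero_trials_is_error(self, small_recording):
        rec = make_recording(n_leads=1, n_trials=2)
        rec.conditions[:] = "neutral"
        with pytest.raises(ValueError, match="no .* trials"):
            ik.compute_ierp(rec, "L000", "smiling")

    def test_planted_amplitude_recovered(self):
        """Averaged peak is within 3 SE of the planted amplitude."""
        amp, sd, n = 3.0, 1.0, 54
        evoked = {"L000": {"smiling": ik.EvokedSpec("smiling", amp, 300.0)}}
        misses = 0
        for seed in range(20):
            rec = make_recording(
                n_leads=1, evoked=evoked, n_trials=n, white_sd=sd, seed=seed
            )
            ierp = ik.compute_ierp(rec, "L000", "smiling")
            peak = ierp.waveform[np.argmin(np.abs(ierp.times_ms - 300.0))]
            # baseline correction adds a small variance term; 3 SE bound
            se = sd / np.sqrt(n) * np.sqrt(1 + 1 / 200)
            misses += abs(peak - amp) > 3 * se
        assert misses <= 2  # ~0.3% expected miss rate per seed

    def test_baseline_correction_idempotent(self):
        rec = make_recording(n_leads=1, n_trials=4, seed=3)
        once = baseline_correct(rec.data[0], rec, ik.DEFAULT_CONFIG)
        twice = baseline_correct(once, rec, ik.DEFAULT_CONFIG)
        np.testing.assert_allclose(once, twice, atol=1e-12)


class TestResponsiveness:
    def test_three_consecutive_bins_not_responsive(self):
        """A difference confined to 60 ms (3 bins) fails the >=4 rule."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((1, 30, 900))
        # huge offset only in bins 5..7 (samples 300..359)
        data[:, :, 300:360] += 50.0
        rec = recording_from_array(data, ["smiling"] * 30)
        res = ik.detect_responsive(rec, "L000", "smiling")
        assert res.max_run_length == 3
        assert not res.responsive

    def test_wide_planted_bump_is_responsive(self):
        evoked = {
            "L000": {"smiling": ik.EvokedSpec("smiling", 5.0, 300.0, 120.0)}
        }
        for seed in range(5):
            rec = make_recording(
                n_leads=1, evoked=evoked, n_trials=54, seed=seed
            )
            assert ik.detect_responsive(rec, "L000", "smiling").responsive

    def test_flag_iff_run_reaches_minimum(self):
        res_p = bin_baseline_pvalues(
            make_recording(n_leads=1, n_trials=10).trials("L000", "smiling"),
            make_recording(n_leads=1, n_trials=10),
        )
        assert res_p.shape == (35,)
        assert np.all((res_p >= 0) & (res_p <= 1))

    def test_fewer_than_two_trials_rejected(self):
        data = np.zeros((1, 2, 900))
        rec = recording_from_array(data, ["smiling", "neutral"])
        with pytest.raises(ValueError, match=">= 2"):
            ik.detect_responsive(rec, "L000", "smiling")

    @given(st.lists(st.booleans(), max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_max_run_length_matches_reference(self, flags):
        best = cur = 0
        for f in flags:
            cur = cur + 1 if f else 0
            best = max(best, cur)
        assert max_run_length(np.array(flags, dtype=bool)) == best


class TestRunLengthNull:
    def test_dp_matches_exhaustive_enumeration(self):
        """DP null rate equals a weighted enumeration over all outcomes."""
        n, p, run = 10, 0.3, 3
        total = 0.0
        for mask in range(2**n):
            bits = [(mask >> i) & 1 for i in range(n)]
            prob = np.prod([p if b else 1 - p for b in bits])
            if max_run_length(np.array(bits, bool)) >= run:
                total += prob
        assert ik.consecutive_run_null_rate(n, p, run) == pytest.approx(
            total, abs=1e-12
        )

    def test_rule_suppresses_per_bin_rate(self):
        rate = ik.consecutive_run_null_rate(35, 0.05, 4)
        assert rate < 0.01
        # bracketed by one fixed run and the union bound over start bins
        assert 0.05**4 <= rate <= 32 * 0.05**4


def splitplot_oracle(group_a, group_b):
    """From-scratch split-plot ANOVA p-values (condition, time, interaction)."""
    n_a, b = group_a.shape
    n_b = group_b.shape[0]
    x = np.concatenate([group_a, group_b])
    n = n_a + n_b
    gm = x.mean()
    subj = x.mean(axis=1)
    cond_means = [group_a.mean(), group_b.mean()]
    ss_between_subj = b * np.sum((subj - gm) ** 2)
    ss_cond = b * (n_a * (cond_means[0] - gm) ** 2 + n_b * (cond_means[1] - gm) ** 2)
    ss_subj_within = ss_between_subj - ss_cond
    time_means = x.mean(axis=0)
    ss_time = n * np.sum((time_means - gm) ** 2)
    cell_a = group_a.mean(axis=0)
    cell_b = group_b.mean(axis=0)
    ss_cells = n_a * np.sum((cell_a - gm) ** 2) + n_b * np.sum(
        (cell_b - gm) ** 2
    )
    ss_inter = ss_cells - ss_cond - ss_time
    ss_total = np.sum((x - gm) ** 2)
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter
    df_cond, df_time = 1, b - 1
    df_subj = n - 2
    df_err = df_subj * df_time
    f_cond = (ss_cond / df_cond) / (ss_subj_within / df_subj)
    f_time = (ss_time / df_time) / (ss_error / df_err)
    f_inter = (ss_inter / df_time) / (ss_error / df_err)
    return (
        sps.f.sf(f_cond, df_cond, df_subj),
        sps.f.sf(f_time, df_time, df_err),
        sps.f.sf(f_inter, df_time, df_err),
    )


class TestSelectivity:
    def test_anova_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((6, 4)) + np.linspace(0, 1, 4)
        b = rng.standard_normal((6, 4))
        got = mixed_anova_pvalues(a, b)
        want = splitplot_oracle(a, b)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_identical_groups_not_selective(self):
        """Duplicating the neutral trials as 'emotional' kills the interaction."""
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((30, 900))
        data = np.concatenate([trials, trials])[None, :, :]
        rec = recording_from_array(
            data, ["smiling"] * 30 + ["neutral"] * 30
        )
        res = ik.test_selectivity(rec, "L000", "smiling_vs_neutral")
        assert res.p_interaction == pytest.approx(1.0, abs=1e-6)
        assert not res.selective
        assert res.posthoc_bins is None and res.peak_latency_ms is None

    def test_planted_difference_selective_with_localised_posthoc(self):
        evoked = {
            "L000": {"smiling": ik.EvokedSpec("smiling", 5.0, 300.0)}
        }
        rec = make_recording(n_leads=1, evoked=evoked, n_trials=54, seed=4)
        res = ik.test_selectivity(rec, "L000", "smiling_vs_neutral")
        assert res.selective
        peak_bin = 300 // 20
        assert res.posthoc_bins[peak_bin]
        assert res.peak_class_ms == 300
        # far-away bins should mostly be unaffected
        assert res.posthoc_bins[:3].sum() <= 1

    def test_null_selectivity_rate_conservative(self):
        """The joint interaction+main-effect criterion stays below alpha."""
        hits = 0
        n_leads = 120
        rec = make_recording(n_leads=n_leads, n_trials=20, seed=77)
        for lead_id in rec.lead_ids:
            hits += ik.test_selectivity(
                rec, lead_id, "smiling_vs_neutral"
            ).selective
        assert hits / n_leads < 0.05

    def test_unknown_contrast_rejected(self, small_recording):
        with pytest.raises(ValueError, match="contrast"):
            ik.test_selectivity(small_recording, "L000", "happy_vs_sad")

    def test_contrast_table_complete(self):
        assert set(CONTRASTS) == {
            "smiling_vs_neutral",
            "fearful_vs_neutral",
            "smiling_vs_fearful",
        }


class TestPeakLatency:
    def _ierp(self, waveform):
        times = np.arange(-200.0, 700.0)
        return ik.IERP("L000", "smiling", np.asarray(waveform), times, 10)

    def _delta(self, t_ms, value=1.0):
        w = np.zeros(900)
        w[int(t_ms) + 200] = value
        return self._ierp(w)

    @pytest.mark.parametrize(
        "latency,expected_class",
        [(320, 300), (150, 200), (49, 100), (10, 100), (550, 500), (650, 500)],
    )
    def test_class_bins_half_open(self, latency, expected_class):
        peak, klass = ik.peak_latency(self._delta(latency))
        assert peak == latency
        assert klass == expected_class

    def test_polarity_free(self):
        peak, _ = ik.peak_latency(self._delta(420, value=-3.0))
        assert peak == 420

    def test_tie_earliest_wins(self):
        w = np.zeros(900)
        w[300] = w[500] = 2.0  # 100 ms and 300 ms
        peak, klass = ik.peak_latency(self._ierp(w))
        assert peak == 100 and klass == 100

    def test_constant_waveform_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ik.peak_latency(self._ierp(np.ones(900)))


class TestPipelineGating:
    def test_selective_subset_of_responsive(self):
        evoked = {
            "L000": {
                "smiling": ik.EvokedSpec("smiling", 5.0, 250.0),
                "fearful": ik.EvokedSpec("fearful", 5.0, 250.0),
            }
        }
        rec = make_recording(n_leads=3, evoked=evoked, n_trials=30, seed=6)
        table = ik.analyze_recording(rec)
        assert len(table) == 3
        for _, row in table.iterrows():
            if row["selective"]:
                assert row["responsive"]
        planted = table.set_index("lead_id").loc["L000"]
        assert planted["responsive"] and planted["selective"]

    def test_detector_and_tester_estimator_api(self):
        rec = make_recording(n_leads=2, n_trials=10, seed=8)
        det = ik.ResponsivenessDetector()
        assert det.get_params()["method"] == "paired"
        det.fit(rec)
        assert det.responsive_.shape == (2, 2)
        tester = ik.SelectivityTester().fit(
            rec, gate={lead: True for lead in rec.lead_ids}
        )
        assert set(tester.frame_["contrast"]) <= {
            "smiling_vs_neutral",
            "fearful_vs_neutral",
        }
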