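"""t-tests, ANOVA, sliding-window onset detection, peak latency, jackknife."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from erplat.containers import epoch_time_axis
from erplat.stats import (
    detect_onset,
    independent_t,
    jackknife_latency_difference,
    jackknife_se,
    one_sample_t,
    one_way_anova,
    peak_latency,
    sliding_window_ttest,
    SlidingWindowResult,
)

from conftest import make_waveform


class TestOneSampleT:
    def test_textbook_example(self):
        res = one_sample_t([0.1, 0.2, 0.3, 0.4])
        assert res.mean == pytest.approx(0.25)
        assert res.sem == pytest.approx(0.0645497, abs=1e-6)
        assert res.statistic == pytest.approx(3.872983, abs=1e-5)
        assert res.df == 3

    def test_matches_scipy(self, rng):
        x = rng.normal(size=24)
        res = one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_c1_amplitude_scale(self, rng):
        """Per-subject window means with mean -0.642 uV and SEM 0.158 uV at
        n=24 give t(23) close to -4.06 (printed as -4.054 from rounded
        inputs)."""
        x = rng.normal(size=24)
        x = (x - x.mean()) / (x.std(ddof=1) / math.sqrt(24))  # mean 0, SEM 1
        values = -0.642 + 0.158 * x / 1.0
        res = one_sample_t(values)
        assert res.df == 23
        assert res.statistic == pytest.approx(-0.642 / 0.158, abs=1e-9)
        assert res.p < 0.001

    def test_degenerate_spread(self):
        res = one_sample_t([2.0, 2.0, 2.0], mu0=2.0)
        assert res.statistic == 0.0 and res.p == 1.0
        res = one_sample_t([2.0, 2.0, 2.0], mu0=0.0)
        assert math.isinf(res.statistic) and res.statistic > 0 and res.p == 0.0


class TestIndependentT:
    def test_hand_computed_example(self):
        res = independent_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-1.224745, abs=1e-5)
        assert res.df == 4

    def test_identical_groups_t_zero(self):
        res = independent_t([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == 0.0

    def test_matches_scipy_pooled(self, rng):
        a, b = rng.normal(size=24), rng.normal(size=24)
        res = independent_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.df == 46  # two 24-subject samples
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestOneWayAnova:
    def test_shifted_groups(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0)
        assert (res.df1, res.df2) == (2, 6)

    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3]] * 3)
        assert res.F == pytest.approx(0.0)

    def test_three_cohorts_df(self, rng):
        groups = [rng.normal(size=24) for _ in range(3)]
        res = one_way_anova(groups)
        assert (res.df1, res.df2) == (2, 69)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, abs=1e-12)


def brute_force_sliding(waves, site, lo, hi, win=20.0, step=2.0, mode="one_sample",
                        group_b=None):
    """Independent re-derivation: enumerate nominal windows, snap edges to the
    nearest samples, test with scipy."""
    time_ms = waves[0].time_ms
    fs = 1000.0 / (time_ms[1] - time_ms[0])
    mids, ts, ps = [], [], []
    m = math.ceil((lo + win / 2) / step) * step
    while m <= hi - win / 2 + 1e-9:
        i0 = int(round((m - win / 2 - time_ms[0]) * fs / 1000.0))
        i1 = int(round((m + win / 2 - time_ms[0]) * fs / 1000.0))
        amps = [w.site_series(site)[i0:i1].mean() for w in waves]
        if mode == "one_sample":
            r = sps.ttest_1samp(amps, 0.0)
        else:
            amps_b = [w.site_series(site)[i0:i1].mean() for w in group_b]
            r = sps.ttest_ind(amps, amps_b, equal_var=True)
        mids.append(m)
        ts.append(r.statistic)
        ps.append(r.pvalue)
        m += step
    return np.array(mids), np.array(ts), np.array(ps)


def brute_force_onset(significant, midpoints, k=5):
    for i in range(len(significant)):
        if all(significant[i:i + k]) and i + k <= len(significant):
            return float(midpoints[i])
    return None


class TestSlidingWindow:
    @pytest.mark.parametrize("fs", [500.0, 512.0])
    def test_matches_brute_force_enumeration(self, fs, rng):
        waves = [make_waveform(rng.normal(size=(1, 200)), fs=fs) for _ in range(8)]
        res = sliding_window_ttest(waves, "POz", (-100.0, 150.0))
        mids, ts, ps = brute_force_sliding(waves, "POz", -100.0, 150.0)
        np.testing.assert_allclose(res.midpoints_ms, mids)
        np.testing.assert_allclose(res.t, ts, atol=1e-10)
        np.testing.assert_allclose(res.p, ps, atol=1e-10)

    def test_independent_mode_matches_brute_force(self, rng):
        a = [make_waveform(rng.normal(size=(1, 200))) for _ in range(6)]
        b = [make_waveform(rng.normal(size=(1, 200))) for _ in range(6)]
        res = sliding_window_ttest(a, "POz", (-100.0, 100.0), mode="independent",
                                  group_b=b)
        mids, ts, ps = brute_force_sliding(a, "POz", -100.0, 100.0,
                                           mode="independent", group_b=b)
        np.testing.assert_allclose(res.t, ts, atol=1e-10)
        np.testing.assert_allclose(res.p, ps, atol=1e-10)

    def test_constant_positive_waveforms_all_significant(self, rng):
        waves = [make_waveform(np.full((1, 200), 1.0) + rng.normal(scale=1e-3, size=(1, 200)))
                 for _ in range(8)]
        res = sliding_window_ttest(waves, "POz", (0.0, 100.0))
        assert res.significant.all()

    def test_midpoint_labels_are_step_multiples(self, rng):
        waves = [make_waveform(rng.normal(size=(1, 200))) for _ in range(4)]
        res = sliding_window_ttest(waves, "POz", (0.0, 100.0))
        assert np.allclose(np.diff(res.midpoints_ms), 2.0)
        assert np.allclose(res.midpoints_ms % 2.0, 0.0)


class TestDetectOnset:
    def make_result(self, flags, start=60.0):
        flags = np.asarray(flags, dtype=bool)
        mids = start + 2.0 * np.arange(flags.size)
        return SlidingWindowResult(site="POz", midpoints_ms=mids,
                                   t=np.zeros(flags.size), p=np.where(flags, 0.01, 0.5),
                                   significant=flags, alpha=0.05,
                                   window_len_ms=20.0, step_ms=2.0, mode="one_sample")

    def test_first_window_of_long_run(self):
        flags = [False, False, True, True, True, True, True, False]
        assert detect_onset(self.make_result(flags)).onset_ms == 64.0

    def test_short_runs_do_not_fire(self):
        flags = [True, True, True, True, False] * 3
        assert detect_onset(self.make_result(flags)).onset_ms is None

    def test_run_longer_than_k_reports_its_start(self):
        flags = [False] + [True] * 9
        assert detect_onset(self.make_result(flags)).onset_ms == 62.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_agrees_with_run_enumeration(self, flags):
        res = self.make_result(flags)
        assert detect_onset(res, k=5).onset_ms == brute_force_onset(flags, res.midpoints_ms)


class TestPeakLatency:
    def test_gaussian_bump_peak(self):
        time_ms = epoch_time_axis(500.0)
        w = make_waveform(np.exp(-0.5 * ((time_ms - 92.0) / 10.0) ** 2)[None, :])
        assert peak_latency(w, "POz", (50.0, 150.0), "positive") == 92.0

    def test_negative_polarity(self):
        time_ms = epoch_time_axis(500.0)
        w = make_waveform(-np.exp(-0.5 * ((time_ms - 80.0) / 10.0) ** 2)[None, :])
        assert peak_latency(w, "POz", (40.0, 120.0), "negative") == 80.0

    def test_tie_breaks_earliest(self):
        time_ms = epoch_time_axis(500.0)
        data = np.zeros_like(time_ms)
        data[time_ms == 80.0] = 1.0
        data[time_ms == 90.0] = 1.0
        w = make_waveform(data[None, :])
        assert peak_latency(w, "POz", (50.0, 150.0), "positive") == 80.0

    def test_flat_window_warns_and_returns_start(self):
        w = make_waveform(np.zeros((1, 400)))
        with pytest.warns(UserWarning):
            assert peak_latency(w, "POz", (50.0, 150.0), "positive") == 50.0

    def test_recovers_planted_c1_latency(self, noiseless_config):
        from erplat.erp import average_condition
        from erplat.synth import simulate_subject_epochs
        ep = simulate_subject_epochs(noiseless_config, 0)
        wave = average_condition(ep, "homogeneous")
        lat = peak_latency(wave, "POz", (50.0, 120.0), "negative")
        assert abs(lat - 80.0) <= 1000.0 / noiseless_config.sampling_rate_hz


class TestJackknife:
    def test_identical_groups_paired(self, rng):
        waves = [make_waveform(np.exp(-0.5 * ((epoch_time_axis(500.0) - 90 - i) / 12) ** 2)[None, :])
                 for i in range(5)]
        res = jackknife_latency_difference(
            waves, waves, design="paired", site_a="POz", site_b="POz",
            search_window_ms=(50.0, 150.0), polarity_a="positive", polarity_b="positive")
        assert res.D_ms == 0.0 and res.t_corrected == 0.0

    def test_linear_statistic_se_equals_sem(self, rng):
        """On leave-one-out means of a scalar sample, the jackknife SE equals
        the classical SEM to machine precision."""
        x = rng.normal(size=24)
        loo_means = np.array([np.delete(x, i).mean() for i in range(x.size)])
        assert jackknife_se(loo_means) == pytest.approx(
            x.std(ddof=1) / math.sqrt(x.size), abs=1e-12)

    def test_matches_exhaustive_oracle_n4(self, rng):
        """Paired jackknife on 4 subjects equals an explicit enumeration of
        all leave-one-out grand averages."""
        time_ms = epoch_time_axis(500.0)
        peaks_a = [88.0, 92.0, 96.0, 90.0]
        peaks_b = [78.0, 82.0, 80.0, 84.0]
        mk = lambda p: np.exp(-0.5 * ((time_ms - p) / 11.0) ** 2)[None, :]
        a = [make_waveform(mk(p) + rng.normal(scale=0.01, size=(1, 400))) for p in peaks_a]
        b = [make_waveform(mk(p) + rng.normal(scale=0.01, size=(1, 400))) for p in peaks_b]
        res = jackknife_latency_difference(
            a, b, design="paired", site_a="POz", site_b="POz",
            search_window_ms=(50.0, 150.0), polarity_a="positive", polarity_b="positive")

        def peak(mat):
            mask = (time_ms >= 50.0) & (time_ms <= 150.0)
            sub = mat[mask]
            return float(time_ms[mask][np.argmax(sub)])

        ga = np.mean([w.data[0] for w in a], axis=0)
        gb = np.mean([w.data[0] for w in b], axis=0)
        D = peak(ga) - peak(gb)
        loo = []
        for i in range(4):
            la = peak(np.mean([w.data[0] for j, w in enumerate(a) if j != i], axis=0))
            lb = peak(np.mean([w.data[0] for j, w in enumerate(b) if j != i], axis=0))
            loo.append(la - lb)
        loo = np.array(loo)
        se = math.sqrt(3 / 4 * ((loo - loo.mean()) ** 2).sum())
        assert res.D_ms == D
        assert res.se_jack_ms == pytest.approx(se, abs=1e-12)
        assert res.df == 3
        assert res.t_corrected == pytest.approx(D / se, abs=1e-9)

    def test_independent_design_two_group_variance(self, rng):
        time_ms = epoch_time_axis(500.0)
        mk = lambda p: np.exp(-0.5 * ((time_ms - p) / 11.0) ** 2)[None, :]
        a = [make_waveform(mk(p) + rng.normal(scale=0.02, size=(1, 400))) for p in (88, 94, 91, 95)]
        b = [make_waveform(mk(p) + rng.normal(scale=0.02, size=(1, 400))) for p in (78, 84, 80)]
        res = jackknife_latency_difference(
            a, b, design="independent", site_a="POz", site_b="POz",
            search_window_ms=(50.0, 150.0), polarity_a="positive", polarity_b="positive")
        assert res.df == 4 + 3 - 2
        assert res.se_jack_ms >= 0.0
        assert res.D_ms == pytest.approx(11.0, abs=4.0)

    def test_planted_shift_recovered(self, rng):
        """A 10-ms latency shift between groups is recovered as D ~= 10."""
        time_ms = epoch_time_axis(500.0)
        mk = lambda p: np.exp(-0.5 * ((time_ms - p) / 11.0) ** 2)[None, :]
        a = [make_waveform(mk(90 + d) + rng.normal(scale=0.02, size=(1, 400)))
             for d in (-2.0, 0.0, 1.0, 2.0)]
        b = [make_waveform(mk(80 + d) + rng.normal(scale=0.02, size=(1, 400)))
             for d in (-1.0, 0.0, 2.0, -2.0)]
        res = jackknife_latency_difference(
            a, b, design="paired", site_a="POz", site_b="POz",
            search_window_ms=(50.0, 150.0), polarity_a="positive", polarity_b="positive")
        assert res.D_ms == pytest.approx(10.0, abs=4.0)

    def test_paired_requires_equal_n(self, rng):
        w = [make_waveform(rng.normal(size=(1, 100))) for _ in range(3)]
        with pytest.raises(ValueError):
            jackknife_latency_difference(
                w, w[:2], design="paired", site_a="POz", site_b="POz",
                search_window_ms=(0.0, 100.0), polarity_a="positive", polarity_b="positive")
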