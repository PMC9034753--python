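"""Vector strength, Rayleigh test, NCCH/PCH correlation metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amtc.psth import BIN_MS, PeriodSegmentation, SmoothedPSTH, bin_psth, \
    kernel_sigma, population_cpsth, segment_periods
from amtc.synth import SyntheticUnitParams, gen_am_trial
from amtc.temporal import (CorrelationHistogram, am_correlation_metrics,
                           latency_in_periods, make_reference, ncch, pch,
                           per_period_peaks, population_latency_stats,
                           rayleigh_significant, scaled_cc,
                           unwrap_peak_latencies, vector_strength)


WINDOW = (100.0, 500.0)


def tiled_psth(mod_hz, shift_ms=0.0, offset=0.0, scale=1.0, t0=0.0, t1=500.0):
    """PSTH equal to the tiled reference envelope, optionally shifted/offset."""
    t = np.arange(t0, t1 - 1e-9, BIN_MS)
    v = scale * 0.5 * (1.0 - np.cos(2 * np.pi * mod_hz * (t - shift_ms) * 1e-3))
    return SmoothedPSTH(t0, v + offset, 15, sigma_ms=1.0)


def nominal_seg(mod_hz, t0=100.0, t1=500.0):
    period = 1000.0 / mod_hz
    return PeriodSegmentation(mod_hz, np.arange(t0, t1 + 1e-9, period))


class TestVectorStrength:
    def test_perfect_locking(self):
        t = 100.0 + 20.0 * np.arange(15)  # identical phase at 50 Hz
        r = vector_strength(t, 50.0, WINDOW)
        assert r.vs == pytest.approx(1.0)

    def test_antiphase_cancels(self):
        t = np.concatenate([100.0 + 20.0 * np.arange(10),
                            110.0 + 20.0 * np.arange(10)])
        assert vector_strength(t, 50.0, WINDOW).vs == pytest.approx(0.0, abs=1e-12)

    def test_quarter_cycle_pair(self):
        t = np.array([100.0, 105.0])  # phases 0 and pi/2 at 50 Hz
        assert vector_strength(t, 50.0, WINDOW).vs == pytest.approx(np.sqrt(2) / 2)

    def test_no_spikes_undefined(self):
        r = vector_strength(np.array([]), 50.0, WINDOW)
        assert r.vs is None and r.n_spikes == 0

    def test_window_filtering(self):
        # spikes before 100 ms are excluded from the analysis
        t = np.array([0.0, 50.0, 100.0])
        assert vector_strength(t, 50.0, WINDOW).n_spikes == 1


class TestRayleigh:
    def test_formula_at_moderate_locking(self):
        # n = 50, vs = 0.5 -> Z = 12.5; finite-n corrected p ~ exp(-12.5)
        from amtc.temporal import _rayleigh_p
        z = 12.5
        expected = np.exp(-z) * (1 + (2 * z - z * z) / (4 * 50))
        assert _rayleigh_p(50, 0.5) == pytest.approx(expected)
        assert expected < 0.01

    def test_zero_vs_not_significant(self):
        t = np.concatenate([100.0 + 20.0 * np.arange(10),
                            110.0 + 20.0 * np.arange(10)])
        r = vector_strength(t, 50.0, WINDOW)
        assert not rayleigh_significant(r, alpha=0.01)
        assert r.rayleigh_p == pytest.approx(1.0, abs=0.01)

    def test_type_i_error_rate_near_alpha(self):
        # uniform phases: rejection rate at alpha = 0.01 over 400 draws
        rng = np.random.default_rng(99)
        rejections = 0
        n_sets = 400
        for _ in range(n_sets):
            t = rng.uniform(100.0, 500.0, size=100)
            rejections += rayleigh_significant(
                vector_strength(t, 50.0, WINDOW), alpha=0.01)
        from scipy.stats import binom
        lo, hi = binom.interval(0.999, n_sets, 0.01)
        assert lo <= rejections <= hi


class TestReference:
    def test_construction_at_50hz(self):
        ref = make_reference(50.0)
        assert ref.n_samples == 100
        assert ref.r[0] == pytest.approx(0.0)
        assert ref.r.max() == pytest.approx(1.0)
        assert int(np.argmax(ref.r)) == 50

    @pytest.mark.parametrize("fm", [10.0, 40.0, 80.0, 160.0])
    def test_offset_corrected_reference_zero_mean(self, fm):
        ref = make_reference(fm)
        assert abs(ref.s.mean()) < 1e-12
        # var of (1 - cos)/2 over a full cycle is 1/8
        assert (ref.s**2).sum() == pytest.approx(ref.n_samples / 8.0)

    def test_too_short_period_rejected(self):
        with pytest.raises(ValueError):
            make_reference(4000.0)


class TestNcch:
    def test_tiled_reference_reaches_one_at_zero_lag(self):
        h = ncch(tiled_psth(50.0), make_reference(50.0), WINDOW)
        assert h.values[0] == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        p = tiled_psth(50.0)
        v = np.zeros_like(p.values)
        v[:250] = 5.0  # response only in the excluded onset
        h = ncch(SmoothedPSTH(0.0, v, 15), make_reference(50.0), WINDOW)
        assert np.all(h.values == 0.0)
        assert h.degenerate

    def test_flat_psth_closed_form(self):
        p = SmoothedPSTH(0.0, np.full(2500, 7.0), 15)
        h = ncch(p, make_reference(50.0), WINDOW)
        np.testing.assert_allclose(h.values, 1 / np.sqrt(1.5), atol=1e-12)

    def test_scale_invariance(self):
        h1 = ncch(tiled_psth(50.0, scale=1.0), make_reference(50.0), WINDOW)
        h2 = ncch(tiled_psth(50.0, scale=37.0), make_reference(50.0), WINDOW)
        np.testing.assert_allclose(h1.values, h2.values, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_on_random_nonnegative_psths(self, seed):
        rng = np.random.default_rng(seed)
        p = SmoothedPSTH(0.0, rng.uniform(0, 100, 2500), 15)
        h = ncch(p, make_reference(50.0), WINDOW)
        assert np.all((h.values >= 0) & (h.values <= 1))


class TestPch:
    def test_offset_invariance_and_unity(self):
        ref = make_reference(50.0)
        h0 = pch(tiled_psth(50.0), ref, WINDOW)
        h7 = pch(tiled_psth(50.0, offset=7.0), ref, WINDOW)
        assert h0.values[0] == pytest.approx(1.0)
        np.testing.assert_allclose(h0.values, h7.values, atol=1e-9)

    def test_ncch_is_not_offset_invariant(self):
        ref = make_reference(50.0)
        h0 = ncch(tiled_psth(50.0), ref, WINDOW)
        h7 = ncch(tiled_psth(50.0, offset=7.0), ref, WINDOW)
        assert not np.allclose(h0.values, h7.values, atol=1e-3)

    def test_antiphase_reaches_minus_one(self):
        ref = make_reference(50.0)
        h = pch(tiled_psth(50.0, shift_ms=10.0), ref, WINDOW)
        assert h.values[0] == pytest.approx(-1.0)

    def test_flat_psth_gives_zero(self):
        p = SmoothedPSTH(0.0, np.full(2500, 7.0), 15)
        h = pch(p, make_reference(50.0), WINDOW)
        np.testing.assert_allclose(h.values, 0.0, atol=1e-9)
        assert h.degenerate

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_offset_invariant_on_random_psths(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 100, 2500)
        ref = make_reference(50.0)
        h = pch(SmoothedPSTH(0.0, v, 15), ref, WINDOW)
        hc = pch(SmoothedPSTH(0.0, v + 13.0, 15), ref, WINDOW)
        assert np.all((h.values >= -1) & (h.values <= 1))
        np.testing.assert_allclose(h.values, hc.values, atol=1e-7)


class TestPerPeriodPeaks:
    def test_shifted_tiling_yields_constant_latency(self):
        h = ncch(tiled_psth(50.0, shift_ms=5.0), make_reference(50.0), WINDOW)
        lats, coeffs = per_period_peaks(h, nominal_seg(50.0))
        np.testing.assert_allclose(lats, 5.0, atol=BIN_MS / 2)
        np.testing.assert_allclose(coeffs, 1.0, atol=1e-9)

    def test_flat_histogram_ties_resolve_earliest(self):
        lags = 100.0 + np.arange(1900) * BIN_MS
        h = CorrelationHistogram(50.0, lags, np.full(1900, 0.4), "ncch")
        lats, coeffs = per_period_peaks(h, nominal_seg(50.0))
        np.testing.assert_allclose(lats, 0.0)
        np.testing.assert_allclose(coeffs, 0.4)

    def test_partially_covered_periods_skipped(self):
        # lags cover exactly the first period; later periods are skipped
        lags = 100.0 + np.arange(100) * BIN_MS
        h = CorrelationHistogram(50.0, lags, np.ones(100), "ncch")
        lats, _ = per_period_peaks(h, nominal_seg(50.0))
        assert lats.size == 1


class TestScaledCC:
    def test_constant_coefficients(self):
        assert scaled_cc([0.7] * 9) == pytest.approx(0.7 * 3.0)

    def test_single_period_identity(self):
        assert scaled_cc([0.7]) == pytest.approx(0.7)

    def test_mixed(self):
        assert scaled_cc([1.0, 0.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scaled_cc([])


class TestLatencyStats:
    def test_mean_and_sd(self):
        mean, sd = population_latency_stats([15.1, 15.3, 14.9])
        assert mean == pytest.approx(15.1)
        assert sd == pytest.approx(0.2)

    def test_single_value_has_no_sd(self):
        assert population_latency_stats([12.0]) == (12.0, None)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=20))
    def test_matches_brute_force(self, xs):
        mean, sd = population_latency_stats(xs)
        n = len(xs)
        m = sum(xs) / n
        v = sum((x - m) ** 2 for x in xs) / (n - 1)
        assert mean == pytest.approx(m)
        assert sd == pytest.approx(np.sqrt(v), abs=1e-9)


class TestLatencyInPeriods:
    @pytest.mark.parametrize("ms,fm,expected", [
        (51.75, 10.0, 0.5175),
        (21.18, 50.0, 1.0590),
        (0.0, 80.0, 0.0),
    ])
    def test_conversion(self, ms, fm, expected):
        assert latency_in_periods(ms, fm) == pytest.approx(expected)


class TestUnwrap:
    @pytest.mark.parametrize("L", [15.0, 18.0, 21.0])
    def test_recovers_position_beyond_one_period(self, L):
        # raw alignment lag is (L - T/2) mod T; the unwrapped position must
        # equal L given an onset-delay estimate near L
        T = 20.0
        raw = np.full(5, (L - T / 2) % T)
        pos = unwrap_peak_latencies(raw, 50.0, onset_delay_ms=L + 0.3)
        np.testing.assert_allclose(pos, L)

    def test_without_onset_estimate_stays_consistent(self):
        raw = np.array([5.0, 5.2, 4.8])
        pos = unwrap_peak_latencies(raw, 50.0, None)
        assert np.ptp(pos) == pytest.approx(np.ptp(raw))


class TestMonotoneDegradation:
    def test_jitter_ladder_degrades_cc_pc_and_vs(self, am50):
        # increasing per-period jitter must monotonically degrade both the
        # Pearson-like coefficient and vector strength (rank correlation)
        from scipy.stats import spearmanr
        jitters = [0.5, 2.0, 4.0, 8.0]
        cc_pc, vs_vals = [], []
        for i, j in enumerate(jitters):
            params = SyntheticUnitParams(spont_rate_hz=1.0,
                                         evoked_spikes_per_period=1.2,
                                         peak_latency_ms=12.0, jitter_ms=j,
                                         lock_fraction=0.9)
            raws, pooled = [], []
            for s in np.random.SeedSequence(300 + i).spawn(20):
                rng = np.random.default_rng(s)
                trials = [gen_am_trial(params, am50, rng).spike_times_ms
                          for _ in range(15)]
                raws.append(bin_psth(trials, (-500.0, 500.0)))
                pooled.append(np.concatenate(trials))
            cpsth = population_cpsth(raws, kernel_sigma(50.0))
            seg = segment_periods(cpsth, 50.0, WINDOW)
            corr = am_correlation_metrics(cpsth, seg, WINDOW)
            cc_pc.append(corr.cc_pc)
            vs_vals.append(vector_strength(np.concatenate(pooled), 50.0,
                                           WINDOW).vs)
        assert spearmanr(jitters, cc_pc).statistic < 0
        assert spearmanr(jitters, vs_vals).statistic < 0
        assert vs_vals[0] > vs_vals[-1]


class TestAmCorrelationMetrics:
    def test_synthetic_latency_recovery(self, am50):
        params = SyntheticUnitParams(spont_rate_hz=0.5,
                                     evoked_spikes_per_period=1.5,
                                     peak_latency_ms=18.0, jitter_ms=0.5,
                                     lock_fraction=1.0)
        raws = []
        for s in np.random.SeedSequence(42).spawn(30):
            rng = np.random.default_rng(s)
            trials = [gen_am_trial(params, am50, rng).spike_times_ms
                      for _ in range(15)]
            raws.append(bin_psth(trials, (-500.0, 500.0)))
        cpsth = population_cpsth(raws, kernel_sigma(50.0))
        seg = segment_periods(cpsth, 50.0, WINDOW)
        corr = am_correlation_metrics(cpsth, seg, WINDOW)
        assert corr.peak_latency_ms == pytest.approx(18.0, abs=0.5)
        assert corr.jitter_ms < 1.0
        assert corr.n_periods >= 18
        assert corr.cc_pc > 1.0


class TestOnsetDelay:
    def test_first_bump_wins_over_taller_later_bump(self):
        from amtc.temporal import onset_delay
        t = np.arange(-500.0, 500.0, BIN_MS)
        v = np.zeros(t.size)
        v += 100.0 * np.exp(-0.5 * ((t - 12.0) / 1.5) ** 2)
        v += 104.0 * np.exp(-0.5 * ((t - 32.0) / 1.5) ** 2)  # slightly taller
        p = SmoothedPSTH(-500.0, v, 15)
        assert onset_delay(p, 50.0) == pytest.approx(12.0, abs=0.4)

    def test_flat_trace_returns_none(self):
        from amtc.temporal import onset_delay
        p = SmoothedPSTH(-500.0, np.full(5000, 3.0), 15)
        assert onset_delay(p, 50.0) is None


class TestNcchNormalizationModes:
    def test_global_mode_is_scaled_numerator(self):
        # the global denominator is lag-independent, so peak locations are
        # those of the raw cross-correlation
        p = tiled_psth(50.0, shift_ms=3.0)
        ref = make_reference(50.0)
        hw = ncch(p, ref, WINDOW, normalization="windowed")
        hg = ncch(p, ref, WINDOW, normalization="global")
        lw, _ = per_period_peaks(hw, nominal_seg(50.0))
        lg, _ = per_period_peaks(hg, nominal_seg(50.0))
        np.testing.assert_allclose(lw, lg, atol=BIN_MS)

    def test_peak_locations_agree_on_synthetic_response(self, am50):
        params = SyntheticUnitParams(spont_rate_hz=1.0,
                                     evoked_spikes_per_period=1.5,
                                     peak_latency_ms=12.0, jitter_ms=1.0,
                                     lock_fraction=0.9)
        raws = []
        for s in np.random.SeedSequence(55).spawn(20):
            rng = np.random.default_rng(s)
            trials = [gen_am_trial(params, am50, rng).spike_times_ms
                      for _ in range(15)]
            raws.append(bin_psth(trials, (-500.0, 500.0)))
        cpsth = population_cpsth(raws, kernel_sigma(50.0))
        seg = segment_periods(cpsth, 50.0, WINDOW)
        ref = make_reference(50.0)
        lw, _ = per_period_peaks(ncch(cpsth, ref, WINDOW, "windowed"), seg)
        lg, _ = per_period_peaks(ncch(cpsth, ref, WINDOW, "global"), seg)
        assert np.median(np.abs(lw - lg)) <= 2 * BIN_MS

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ncch(tiled_psth(50.0), make_reference(50.0), WINDOW, "other")
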