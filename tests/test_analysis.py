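"""Baseline statistics, onset detection, rate fits, derived ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flowshock import (baseline_stats, compare_to_prediction, detect_onset,
                       fit_linear_rate, fit_washout, fold_increase,
                       percent_reduction, predict_series, volume_changes,
                       derived_quantities)
from flowshock.analysis import BaselineStats

from conftest import make_series


class TestBaseline:
    def test_constant_series(self):
        s = make_series(np.full(15, 130.6))
        b = baseline_stats(s, (0, 15))
        assert b.mean == pytest.approx(130.6)
        assert b.sd == pytest.approx(0.0, abs=1e-9)
        assert b.n == 15

    def test_window_outside_series_raises(self):
        s = make_series(np.full(15, 130.6))
        with pytest.raises(ValueError):
            baseline_stats(s, (100, 120))

    def test_replay_baseline_recovers_truth(self, default_replay):
        """15 synthetic tap-water bins: mean within 3 sigma/sqrt(15)."""
        b = default_replay.baseline_tcc
        sigma = 130.6 / np.sqrt(914.2)  # Poisson-propagated bin SD
        assert b.n == 15
        assert abs(b.mean - 130.6) <= 3 * sigma / np.sqrt(15)


class TestOnset:
    def test_flat_series_never_triggers(self):
        s = make_series(np.full(40, 100.0))
        b = BaselineStats(mean=100.0, sd=1.0, n=15, window=(0, 15))
        assert detect_onset(s, b, 3, 2) is None

    def test_step_detected_at_its_bin(self):
        c = np.full(40, 100.0)
        c[25:] += 10 * 2.0  # +10 sd step at bin 25
        s = make_series(c)
        b = BaselineStats(mean=100.0, sd=2.0, n=15, window=(0, 15))
        assert detect_onset(s, b, 3, 1) == 25.0

    def test_downward_step_detected(self):
        c = np.full(40, 100.0)
        c[30:] = 50.0
        s = make_series(c)
        b = BaselineStats(mean=100.0, sd=2.0, n=15, window=(0, 15))
        assert detect_onset(s, b, 3, 2, direction="down") == 30.0

    def test_zero_sd_any_deviation_triggers(self):
        c = np.full(40, 100.0)
        c[20:] = 100.5
        s = make_series(c)
        b = BaselineStats(mean=100.0, sd=0.0, n=15, window=(0, 15))
        assert detect_onset(s, b, 3, 1) == 20.0

    def test_monotone_in_k_sigma(self):
        """A larger k never yields an earlier onset."""
        rng = np.random.default_rng(0)
        c = np.full(60, 100.0) + rng.normal(0, 2, 60)
        c[30:] += np.linspace(0, 40, 30)  # gradual rise
        s = make_series(c)
        b = BaselineStats(mean=100.0, sd=2.0, n=15, window=(0, 15))
        onsets = [detect_onset(s, b, k, 2) for k in (1, 2, 3, 5, 8)]
        prev = -np.inf
        for o in onsets:
            val = np.inf if o is None else o
            assert val >= prev
            prev = val


class TestLinearRate:
    def test_exact_line_recovered(self):
        t = np.arange(40) + 0.5
        s = make_series(600 - 10.6 * t)
        fit = fit_linear_rate(s, (0, 40))
        assert fit.slope == pytest.approx(-10.6, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_zero_slope(self):
        fit = fit_linear_rate(make_series(np.full(10, 55.0)), (0, 10))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_window(self):
        with pytest.raises(ValueError):
            fit_linear_rate(make_series([1.0, 2.0]), (0, 2))


class TestWashoutFit:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(35) + 0.5
        s = make_series(130.6 + 424.3 * np.exp(-0.2 * t))
        fit = fit_washout(s, (0, 35), floor=130.6)
        assert fit.ok
        assert fit.rate == pytest.approx(0.2, abs=1e-6)
        assert fit.asymptote == pytest.approx(130.6, abs=1e-3)

    def test_constant_series_fails_explicitly(self):
        fit = fit_washout(make_series(np.full(20, 130.6)), (0, 20))
        assert not fit.ok
        assert "unidentifiable" in fit.message

    def test_too_few_bins(self):
        fit = fit_washout(make_series([5.0, 4.0, 3.0]), (0, 3))
        assert not fit.ok

    def test_poisson_noise_recovery_single_seed(self):
        rng = np.random.default_rng(42)
        t = np.arange(35) + 0.5
        truth = 130.6 + 424.3 * np.exp(-0.2 * t)
        counts = rng.poisson(truth * 7.0)
        s = make_series(counts / 7.0)
        fit = fit_washout(s, (0, 35), floor=130.6)
        assert fit.ok
        assert fit.rate == pytest.approx(0.2, rel=0.2)


class TestDerived:
    def test_printed_reduction(self):
        assert percent_reduction(383.3, 19.6) == pytest.approx(94.9, abs=0.05)

    def test_printed_folds(self):
        f, r = fold_increase(679.4, 130.6)
        assert f == pytest.approx(5.20, abs=0.01)
        assert r == 5
        f, r = fold_increase(383.3, 99.6)
        assert r == 4

    def test_no_change(self):
        assert percent_reduction(50.0, 50.0) == 0.0

    def test_zero_denominators(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)
        with pytest.raises(ValueError):
            fold_increase(1.0, 0.0)

    def test_volume_changes(self):
        assert volume_changes(0.2, 15) == pytest.approx(3.0)

    @given(before=st.floats(1, 1e4), after=st.floats(0, 1e4),
           scale=st.floats(0.01, 100))
    def test_scale_invariance(self, before, after, scale):
        assert percent_reduction(before, after) == pytest.approx(
            percent_reduction(before * scale, after * scale), rel=1e-9)
        f1, _ = fold_increase(after + 1, before)
        f2, _ = fold_increase((after + 1) * scale, before * scale)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_bundle(self):
        d = derived_quantities(383.3, 19.6, 679.4, 130.6, 0.2, 15)
        assert d["fold_increase_rounded"] == 5
        assert d["volume_changes"] == pytest.approx(3.0)


class TestCompare:
    def test_identical_series_gives_zero(self):
        pred = predict_series()
        # sample the prediction at bin centers as a perfect measurement
        t = np.arange(80) + 0.5
        s = make_series(pred.at(t, "tcc"))
        rep = compare_to_prediction(s, pred)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.lag_min == 0.0

    def test_one_bin_shift_detected_as_1_min_lag(self):
        pred = predict_series()
        t = np.arange(79) + 0.5
        s = make_series(pred.at(t, "tcc"))
        s.bin_start_min = s.bin_start_min + 1.0  # measurement delayed 1 min
        rep = compare_to_prediction(s, pred)
        assert rep.lag_min == pytest.approx(1.0)

    def test_swapping_roles_negates_residuals_preserves_rmse(self):
        from flowshock import Trajectory

        pred = predict_series()
        t = np.arange(80) + 0.5
        rng = np.random.default_rng(3)
        meas = np.abs(pred.at(t, "tcc") + rng.normal(0, 5, 80))
        rep = compare_to_prediction(make_series(meas), pred)
        # swap: the noisy values become the "prediction", the prediction's
        # samples become the "measurement"
        zeros = np.zeros_like(t)
        swapped_pred = Trajectory(time=t, volume=zeros + 500, tcc=meas,
                                  icc=zeros, chlorine=zeros,
                                  wastewater_fraction=zeros,
                                  dilution_rate=zeros)
        rep2 = compare_to_prediction(make_series(pred.at(t, "tcc")),
                                     swapped_pred)
        assert rep2.residuals == pytest.approx(-rep.residuals)
        assert rep2.rmse == pytest.approx(rep.rmse)

    def test_no_overlap_raises(self):
        pred = predict_series()
        s = make_series([1.0, 2.0, 3.0, 4.0], start_min=500.0)
        with pytest.raises(ValueError):
            compare_to_prediction(s, pred)
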