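"""Mass-balance model: arithmetic identities, closed forms, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowshock import (ExperimentConfig, KineticParams, predict_series,
                       simulate_experiment, washout_concentration,
                       volume_fraction_added, chlorine_dose_concentration)
from flowshock.reactor import DegenerateInputError, _batch_mix


class TestVolumeFraction:
    @pytest.mark.parametrize("rate,elapsed,v0,expected", [
        (3, 1, 500, 3 / 503),          # ~0.6 % (v/v) after one minute
        (0, 10, 500, 0.0),
        (3, 5, 500, 15 / 515),
    ])
    def test_values(self, rate, elapsed, v0, expected):
        assert volume_fraction_added(rate, elapsed, v0) == pytest.approx(expected)

    def test_one_minute_share_rounds_to_0_6_percent(self):
        assert round(100 * volume_fraction_added(3, 1, 500), 1) == 0.6

    def test_zero_total_volume_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            volume_fraction_added(0, 5, 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            volume_fraction_added(-1, 1, 500)


class TestWashout:
    def test_t_zero_identity(self):
        assert washout_concentration(679.4, 130.6, 0.2, 0) == pytest.approx(679.4)

    def test_three_volume_changes_leave_5_percent_excess(self):
        c0, cin = 679.4, 130.6
        c = washout_concentration(c0, cin, 0.2, 15)
        assert (c - cin) / (c0 - cin) == pytest.approx(np.exp(-3), rel=1e-12)

    @given(c=st.floats(0, 1e4), d=st.floats(0, 2), t=st.floats(0, 100))
    def test_fixed_point(self, c, d, t):
        assert washout_concentration(c, c, d, t) == pytest.approx(c, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            washout_concentration(1, 0, 0.2, -1)


class TestChlorineDose:
    @pytest.mark.parametrize("args,expected", [
        ((72, 2.5, 5, 500), 1.8),
        ((72, 2.5, 0, 500), 0.0),
        ((72, 2.5, 5, 527.5), 72 * 2.5 * 5 / 527.5),  # ~1.706
    ])
    def test_values(self, args, expected):
        assert chlorine_dose_concentration(*args) == pytest.approx(expected)

    def test_zero_reference_volume(self):
        with pytest.raises(DegenerateInputError):
            chlorine_dose_concentration(72, 2.5, 5, 0)


class TestPrediction:
    def test_baseline_phase_constant_at_tap_level(self):
        pred = predict_series()
        assert np.all(pred.tcc[:16] == pytest.approx(130.6))
        assert np.all(pred.icc[:16] == pytest.approx(99.6))

    def test_plateau_matches_mixing_mass_balance(self):
        # one-line oracle: (500*130.6 + 15*14700) / 515
        pred = predict_series()
        expected = (500 * 130.6 + 15 * 14700) / 515
        assert pred.tcc[20] == pytest.approx(expected)
        assert expected == pytest.approx(554.95, abs=0.01)

    def test_washout_closed_form_on_grid(self):
        pred = predict_series()
        plateau = pred.tcc[30]
        t = pred.time[pred.time > 45]
        expected = washout_concentration(plateau, 130.6, 0.2, t - 45)
        assert pred.tcc[pred.time > 45] == pytest.approx(expected, rel=1e-12)
        # spot value five minutes into washout: excess reduced to 1/e
        assert pred.at(50, "tcc") == pytest.approx(
            130.6 + (plateau - 130.6) * np.exp(-1.0))

    def test_four_phase_shape(self):
        """Constant -> rising -> constant -> exponential return to baseline."""
        pred = predict_series()
        t = pred.time
        base = pred.tcc[(t >= 0) & (t <= 15)]
        assert np.ptp(base) == 0
        rise = pred.tcc[(t >= 15) & (t <= 20)]
        assert np.all(np.diff(rise) > 0)
        hold = pred.tcc[(t >= 20) & (t <= 45)]
        assert np.ptp(hold) < 1e-9
        fall = pred.tcc[t >= 45]
        assert np.all(np.diff(fall) < 0)
        assert pred.tcc[-1] == pytest.approx(130.6, rel=0.01)

    def test_wastewater_share_exceeds_70_percent_at_end_of_addition(self):
        pred = predict_series()
        assert pred.at(20, "wastewater_fraction") == pytest.approx(
            15 * 14700 / (500 * 130.6 + 15 * 14700))
        assert pred.at(20, "wastewater_fraction") > 0.70
        # at one minute in, the share is ~40 %, not yet 70 %
        assert 0.3 < pred.at(16, "wastewater_fraction") < 0.5

    def test_dilution_rate_is_0_2_per_min(self):
        pred = predict_series()
        assert pred.dilution_rate[pred.time >= 45] == pytest.approx(0.2)
        assert np.all(pred.dilution_rate[pred.time < 45] == 0)


class TestSimulation:
    def test_zero_kinetics_reduces_to_pure_mixing(self):
        sim = simulate_experiment(kinetics=KineticParams.zero())
        pred = predict_series(dilution_volume="tracked")
        assert sim.tcc == pytest.approx(pred.tcc, rel=1e-9)
        assert sim.icc == pytest.approx(pred.icc, rel=1e-9)
        assert sim.chlorine == pytest.approx(pred.chlorine, abs=1e-9)

    def test_cell_number_conservation(self):
        """Cells in + injected - washed out = cells in reactor, <0.1% error."""
        sim = simulate_experiment(kinetics=KineticParams.zero())
        t = sim.time
        initial = 500 * 130.6
        injected = 14700 * 3 * np.clip(t - 15, 0, 5)
        tap_in = 130.6 * 100 * np.clip(t - 45, 0, None)
        in_reactor = sim.tcc * sim.volume
        balance = in_reactor + sim.tcc_washed_out - injected - tap_in - initial
        scale = initial + injected + tap_in
        assert np.max(np.abs(balance) / scale) < 1e-3

    def test_chlorine_batch_demand_closed_form(self):
        """First-order chlorine decay in the batch reaction window."""
        kin = KineticParams()
        sim = simulate_experiment(kinetics=kin)
        m = (sim.time >= 36) & (sim.time <= 44)
        t = sim.time[m]
        cl0 = sim.at(36, "chlorine")
        expected = cl0 * np.exp(-kin.chlorine_demand_rate * (t - 36))
        assert sim.chlorine[m] == pytest.approx(expected, rel=1e-3)

    def test_icc_never_exceeds_tcc_default(self):
        sim = simulate_experiment()
        assert np.all(sim.icc <= sim.tcc + 1e-9)

    @given(kill=st.floats(0, 5), decay=st.floats(0, 30),
           demand=st.floats(0, 0.3))
    @settings(max_examples=15)
    def test_icc_never_exceeds_tcc_property(self, kill, decay, demand):
        kin = KineticParams(icc_kill_rate=kill, tcc_decay_rate=decay,
                            chlorine_demand_rate=demand)
        cfg = ExperimentConfig(time_step=5.0)
        sim = simulate_experiment(cfg, kin, step=0.05)
        assert np.all(sim.icc <= sim.tcc + 1e-9)
        assert np.all(sim.tcc >= 0)
        assert np.all((sim.wastewater_fraction >= 0)
                      & (sim.wastewater_fraction <= 1 + 1e-12))

    def test_icc_monotone_in_kill_rate(self):
        """A higher kill rate never leaves more intact cells at any time."""
        previous = None
        for k in (0.0, 0.3, 0.8, 1.5, 3.0):
            sim = simulate_experiment(
                kinetics=KineticParams(icc_kill_rate=k), step=0.02)
            if previous is not None:
                assert np.all(sim.icc <= previous + 1e-9)
            previous = sim.icc

    def test_icc_collapse_within_4_min_of_chlorine_arrival(self):
        """Intact counts fall from ~383 to <30 cells/ul within 4 minutes."""
        kin = KineticParams()
        sim = simulate_experiment(kinetics=kin, step=0.01)
        dense = simulate_experiment(
            ExperimentConfig(time_step=0.25), kin, step=0.01)
        arrival = dense.time[dense.chlorine > kin.kill_threshold][0]
        assert sim.at(30, "icc") > 380
        assert dense.at(arrival + 4, "icc") < 30
        # implied kill rate bound: k >= ln(383/30)/4
        assert kin.icc_kill_rate >= np.log(383 / 30) / 4

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            simulate_experiment(step=0)
        with pytest.raises(ValueError):
            simulate_experiment(step=3.0)  # larger than the output grid


@given(c0=st.floats(0, 1000), cin=st.floats(0, 20000),
       rate=st.floats(0.1, 10), tau=st.floats(0, 5))
def test_batch_mix_conserves_cells(c0, cin, rate, tau):
    v0 = 500.0
    c = _batch_mix(c0, cin, rate, tau, v0)
    assert c * (v0 + rate * tau) == pytest.approx(v0 * c0 + rate * tau * cin)
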