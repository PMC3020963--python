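"""Electrochemical driving-force conversion and tau interpolation."""

import numpy as np
import pytest

from deactkit import cohorts
from deactkit.driving_force import (
    build_curve,
    tau_at_driving_force,
    to_driving_force,
    voltage_at_driving_force,
)
from deactkit.preprocess import subtract_leak
from deactkit.synthetic import deactivation_protocol, simulate_sweepset
from deactkit.tail_kinetics import TailFit, FitWindow, fit_tails

WT_DG0, WT_ZG = -6.8, 3.0378


def _fits_from_law(voltages, tau_fn):
    return [
        TailFit(
            voltage=v, tau_fast=tau_fn(v), tau_slow=5 * tau_fn(v),
            a_fast=-1.0, a_slow=-0.2, offset=0.0, rel_amp_fast=0.83,
            fit_window=FitWindow(0.0, 100.0), rss=0.0, converged=True,
        )
        for v in voltages
    ]


class TestConversion:
    def test_reported_wt_values_give_minus_28_37_at_minus_120(self):
        # direct arithmetic: -(-6.8 - 3.0378*96.485*(-0.120))
        assert to_driving_force(-120.0, WT_DG0, WT_ZG) == pytest.approx(
            -28.37, abs=0.01
        )

    def test_df_vanishes_at_the_midpoint_voltage(self):
        v_half = 1000.0 * WT_DG0 / (WT_ZG * 96.485)
        assert to_driving_force(v_half, WT_DG0, WT_ZG) == pytest.approx(0.0, abs=1e-9)

    def test_zero_gating_charge_makes_df_voltage_independent(self):
        df = to_driving_force(np.array([-160.0, -60.0, 0.0]), -5.0, 0.0)
        np.testing.assert_allclose(df, 5.0)

    def test_df_is_affine_and_increasing_in_voltage(self):
        e = np.arange(-160.0, -50.0, 10.0)
        df = to_driving_force(e, WT_DG0, WT_ZG)
        steps = np.diff(df)
        assert np.all(steps > 0)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-12)

    def test_voltage_at_driving_force_inverts_conversion(self):
        e = voltage_at_driving_force(-30.0, WT_DG0, WT_ZG)
        assert to_driving_force(e, WT_DG0, WT_ZG) == pytest.approx(-30.0, abs=1e-12)


class TestInterpolation:
    def _curve(self):
        volts = np.arange(-160.0, -59.0, 10.0)
        law = lambda v: 33.7 * np.exp((v + 120.0) / 33.13)
        return build_curve(_fits_from_law(volts, law), WT_DG0, WT_ZG, "WT")

    def test_target_at_a_node_returns_that_tau(self):
        curve = self._curve()
        i = 3
        assert tau_at_driving_force(curve, float(curve.df[i])) == pytest.approx(
            float(curve.tau_fast[i]), rel=1e-12
        )

    def test_log_linear_law_is_interpolated_exactly_between_nodes(self):
        """tau = a*exp(b*DF) sampled at nodes: log-tau interpolation is
        exact everywhere, not just at the nodes."""
        curve = self._curve()
        for target in (-35.0, -30.0, -22.5):
            e = voltage_at_driving_force(target, WT_DG0, WT_ZG)
            expected = 33.7 * np.exp((e + 120.0) / 33.13)
            assert tau_at_driving_force(curve, target) == pytest.approx(
                expected, rel=1e-9
            )

    def test_extrapolation_requires_opt_in(self):
        curve = self._curve()
        with pytest.raises(ValueError, match="outside the measured span"):
            tau_at_driving_force(curve, -60.0)
        val = tau_at_driving_force(curve, -60.0, allow_extrapolation=True)
        assert val > 0

    def test_curve_points_are_sorted_by_df(self):
        curve = self._curve()
        assert np.all(np.diff(curve.df) > 0)


def test_pipeline_recovers_the_realized_cohort_truth():
    """The full chain recovers the mean tau@-30 kJ/mol of the *realized*
    jittered cohort to within ~3%: the measurement error is small compared
    with the between-oocyte spread it has to average over."""
    from deactkit.reproduce import driving_force_cohort

    seed, offset, n = 21, 900, 6
    res = driving_force_cohort("WT", n, seed, id_offset=offset)
    m = cohorts.paper_model("WT")
    true = []
    for i in range(n):
        mm = m.jittered(seed, offset + i)
        true.append(
            float(mm.tau_fast(voltage_at_driving_force(-30.0, mm.dg0, mm.z_g)))
        )
    assert np.mean(res.tau_at_target) == pytest.approx(np.mean(true), rel=0.03)


def test_equal_tau_of_df_constructs_agree_at_target_despite_shifted_activation():
    """Two constructs with identical tau(DF) but different activation
    energetics have different tau at -120 mV yet the same tau at the
    equivalent driving force: the driving-force correction removes a pure
    activation shift."""
    efold = cohorts.DEFAULT_EFOLD_MV
    dg0_b = -3.0
    shift_mv = 1000.0 * (dg0_b - WT_DG0) / (WT_ZG * 96.485)
    wt = cohorts.paper_model("WT", noise_sd_frac=0.0, oocyte_cv=0.0, g_leak=0.0)
    from deactkit.models import GatingModel
    b = GatingModel.from_midpoint_energy(
        "B", v_half=1000.0 * dg0_b / (WT_ZG * 96.485), dg0=dg0_b,
        tau_fast_ref=wt.tau_fast_ref * np.exp(-shift_mv / efold),
        tau_slow_ref=wt.tau_slow_ref * np.exp(-shift_mv / efold),
        tau_voltage_efold=efold,
        noise_sd_frac=0.0, oocyte_cv=0.0, g_leak=0.0,
    )
    proto = deactivation_protocol()
    taus = {}
    for m in (wt, b):
        ss = subtract_leak(simulate_sweepset(m, proto, 0, 0))
        fits = fit_tails(ss)
        curve = build_curve(fits, m.dg0, m.z_g, m.construct_label)
        taus[m.construct_label] = {
            "at_target": tau_at_driving_force(curve, -30.0),
            "at_-120": [f.tau_fast for f in fits if f.voltage == -120.0][0],
        }
    # raw tau at -120 differs by the activation shift ...
    assert taus["B"]["at_-120"] < 0.8 * taus["WT"]["at_-120"]
    # ... but tau at the equivalent driving force agrees
    assert taus["B"]["at_target"] == pytest.approx(
        taus["WT"]["at_target"], rel=0.01
    )
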