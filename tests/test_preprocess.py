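"""Leak estimation and subtraction contracts."""

import numpy as np
import pytest

from deactkit import cohorts
from deactkit.models import Epoch, SweepSet, VoltageProtocol
from deactkit.preprocess import (
    AlreadySubtractedError,
    LeakCheckMissingError,
    estimate_leak,
    slice_epoch,
    subtract_leak,
)
from deactkit.synthetic import deactivation_protocol, simulate_sweepset


def _leak_only_model(g_leak):
    return cohorts.paper_model(
        "WT", g_max=0.0, g_leak=g_leak, noise_sd_frac=0.0, oocyte_cv=0.0
    )


def test_noiseless_leak_is_recovered_exactly(deact_proto):
    ss = simulate_sweepset(_leak_only_model(1.0), deact_proto, 0, 0)
    est = estimate_leak(ss)
    assert est.g_leak_hat == pytest.approx(1.0, abs=1e-12)
    assert est.baseline_at_holding == pytest.approx(0.0, abs=1e-12)
    assert est.source_step == (-90.0, -70.0)
    assert not est.negative_conductance


def test_subtraction_zeroes_a_pure_leak_recording(deact_proto):
    ss = simulate_sweepset(_leak_only_model(0.7), deact_proto, 0, 0)
    sub = subtract_leak(ss)
    np.testing.assert_allclose(sub.currents, 0.0, atol=1e-12)
    assert sub.is_leak_subtracted
    # re-estimation on the subtracted data finds no leak
    resub = estimate_leak(sub)
    assert resub.g_leak_hat == pytest.approx(0.0, abs=1e-12)


def test_linearity_leak_removed_at_every_voltage(deact_proto):
    """Leak estimated at the +20 mV check removes the leak at every level
    in the linear range for the linear generator."""
    ss = simulate_sweepset(_leak_only_model(0.5), deact_proto, 0, 0)
    sub = subtract_leak(ss)
    for k in range(len(deact_proto.epochs)):
        _, cur = slice_epoch(sub, k)
        np.testing.assert_allclose(cur, 0.0, atol=1e-12)


def test_zero_leak_subtraction_is_identity_on_ionic_current(
    wt_clean, deact_proto
):
    """With no leak in the generator, subtraction leaves the ionic current
    essentially untouched (the only residue is the vanishing channel
    current
    flowing during the +20 mV check step, which maps to <1% of the peak
    current through the estimated-leak line)."""
    ss = simulate_sweepset(wt_clean, deact_proto, 0, 0, cap_amp_factor=0.0)
    sub = subtract_leak(ss)
    np.testing.assert_allclose(sub.currents, ss.ideal_currents, atol=1e-2)


def test_tail_amplitude_matches_generator_ionic_component(
    wt_model, deact_proto
):
    """After subtraction on noisy data the tail agrees with the stored
    ionic ground truth to within the noise scale."""
    ss = simulate_sweepset(wt_model, deact_proto, 0, 3)
    sub = subtract_leak(ss)
    sl = deact_proto.epoch_slices()[deact_proto.sweep_variable]
    s = ss.sweep_index(-120.0)
    # compare away from the capacitive transient
    seg = slice(sl.start + 40, sl.stop)
    resid = sub.currents[s, seg] - ss.ideal_currents[s, seg]
    peak = np.max(np.abs(ss.ideal_currents[s, sl]))
    noise_sd = wt_model.noise_sd_frac * peak
    assert np.std(resid) < 3 * noise_sd
    # any systematic offset (residual leak-estimate bias) stays below 1%
    # of the tail amplitude
    assert abs(np.mean(resid)) < 0.01 * peak


def test_double_subtraction_is_rejected(wt_clean, deact_proto):
    ss = simulate_sweepset(wt_clean, deact_proto, 0, 0)
    sub = subtract_leak(ss)
    with pytest.raises(AlreadySubtractedError):
        subtract_leak(sub)


def test_noisy_leak_estimate_within_analytic_standard_error():
    """Plateau-mean leak estimate: |g_hat - g| < 3 SE, with the SE of the
    difference of two plateau means computed in closed form."""
    g_true = 0.5  # uS
    holding, check = -90.0, -70.0
    proto = VoltageProtocol(
        name="leakcheck",
        holding=holding,
        epochs=(Epoch(holding, 100.0), Epoch(check, 100.0), Epoch(-120.0, 25.0)),
        sweep_variable=2,
        sweep_levels=(-120.0,),
        sample_interval=0.5,
    )
    rng = np.random.default_rng(8)
    v = proto.voltage_matrix()
    leak = g_true * (v - holding) / 1000.0
    sd = 0.01 * abs(g_true * (check - holding) / 1000.0)  # 1% of the step
    ss = SweepSet(
        protocol=proto,
        time=proto.time(),
        currents=leak + rng.normal(0.0, sd, size=leak.shape),
        construct_label="synthetic-leak",
        oocyte_id=0,
        rng_seed=8,
    )
    est = estimate_leak(ss)
    n = 100  # trailing half of each 200-sample epoch
    se = sd * np.sqrt(2.0 / n) / (check - holding) * 1000.0
    assert abs(est.g_leak_hat - g_true) < 3 * se


def test_missing_leak_check_epoch_raises(wt_clean):
    proto = deactivation_protocol()
    bad = VoltageProtocol(
        name="nocheck",
        holding=proto.holding,
        epochs=proto.epochs,
        sweep_variable=proto.sweep_variable,
        sweep_levels=proto.sweep_levels,
        sample_interval=proto.sample_interval,
        leak_check_level=-55.0,  # no epoch sits at this level
    )
    ss = simulate_sweepset(wt_clean, bad, 0, 0)
    with pytest.raises(LeakCheckMissingError):
        estimate_leak(ss)


class TestSliceEpoch:
    def test_first_and_last_epoch_bounds(self, wt_clean, deact_proto):
        ss = simulate_sweepset(wt_clean, deact_proto, 0, 0)
        t0, c0 = slice_epoch(ss, 0)
        tn, cn = slice_epoch(ss, len(deact_proto.epochs) - 1)
        assert t0[0] == 0.0 and tn[0] == 0.0  # re-zeroed time origin
        total = sum(
            slice_epoch(ss, k)[1].shape[1]
            for k in range(len(deact_proto.epochs))
        )
        assert total == ss.currents.shape[1]

    def test_out_of_range_index(self, wt_clean, deact_proto):
        ss = simulate_sweepset(wt_clean, deact_proto, 0, 0)
        with pytest.raises(IndexError):
            slice_epoch(ss, 99)
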