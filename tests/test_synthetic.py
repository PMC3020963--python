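"""Generator contracts: closed forms, determinism, cohort structure."""

import numpy as np
import pytest

from deactkit import cohorts
from deactkit.models import ProtocolRangeError
from deactkit.synthetic import (
    deactivation_protocol,
    make_cohort,
    simulate_sweepset,
)


def _open_fraction_recursion(model, levels, durations, holding):
    """Independent oracle: per-epoch analytic relaxation of open fraction.

    Returns the open-fraction trajectory entering each epoch and a callable
    p(t) for the last epoch.
    """
    p = float(model.p_inf(holding))
    for lvl, dur in zip(levels[:-1], durations[:-1]):
        p_inf = float(model.p_inf(lvl))
        if p_inf >= p:
            p = p_inf + (p - p_inf) * np.exp(-dur / model.tau_act)
        else:
            a = model.amp_fast_frac(lvl)
            tf, ts = float(model.tau_fast(lvl)), float(model.tau_slow(lvl))
            p = p_inf + (p - p_inf) * (
                a * np.exp(-dur / tf) + (1 - a) * np.exp(-dur / ts)
            )
    lvl = levels[-1]
    p_inf = float(model.p_inf(lvl))
    a = model.amp_fast_frac(lvl)
    tf, ts = float(model.tau_fast(lvl)), float(model.tau_slow(lvl))

    def p_of_t(t):
        return p_inf + (p - p_inf) * (
            a * np.exp(-t / tf) + (1 - a) * np.exp(-t / ts)
        )

    return p_of_t


def test_noiseless_tail_matches_analytic_biexponential(wt_clean, deact_proto):
    """The noiseless, leak-free tail is the closed-form bi-exponential."""
    ss = simulate_sweepset(wt_clean, deact_proto, 0, 0, cap_amp_factor=0.0)
    s = ss.sweep_index(-120.0)
    sl = deact_proto.epoch_slices()[deact_proto.sweep_variable]
    t = ss.time[sl] - ss.time[sl.start]
    levels = deact_proto.epoch_levels(s)
    p_of_t = _open_fraction_recursion(
        wt_clean, levels, deact_proto.durations, deact_proto.holding
    )
    expected = wt_clean.g_max * p_of_t(t) * (-120.0 - wt_clean.e_rev) / 1000.0
    np.testing.assert_allclose(ss.currents[s, sl], expected, rtol=1e-10, atol=1e-14)
    np.testing.assert_allclose(ss.ideal_currents[s, sl], expected, rtol=1e-10, atol=1e-14)


def test_simulation_is_bit_reproducible(wt_model, deact_proto):
    a = simulate_sweepset(wt_model, deact_proto, 3, 42)
    b = simulate_sweepset(wt_model, deact_proto, 3, 42)
    c = simulate_sweepset(wt_model, deact_proto, 4, 42)
    assert np.array_equal(a.currents, b.currents)
    assert not np.array_equal(a.currents, c.currents)


def test_out_of_range_protocols_are_rejected(wt_model):
    proto = deactivation_protocol(v_stop=-170.0)
    with pytest.raises(ProtocolRangeError):
        simulate_sweepset(wt_model, proto, 0, 0)


def test_steady_state_reached_after_long_step(wt_clean, act_proto):
    """A 4-s step relaxes the open fraction to the Boltzmann value."""
    ss = simulate_sweepset(wt_clean, act_proto, 0, 0, cap_amp_factor=0.0)
    step_idx = act_proto.sweep_variable
    sl = act_proto.epoch_slices()[step_idx]
    for s, level in enumerate(act_proto.sweep_levels):
        drive = (level - wt_clean.e_rev) / 1000.0
        if abs(drive) < 1e-9:
            continue
        p_end = ss.ideal_currents[s, sl.stop - 1] / (wt_clean.g_max * drive)
        assert p_end == pytest.approx(float(wt_clean.p_inf(level)), abs=1e-6)


def test_fitted_tau_decreases_toward_negative_voltages(wt_clean, deact_proto):
    """Simulated fast time constants shrink monotonically with repolarization."""
    from deactkit.preprocess import slice_epoch
    from deactkit.tail_kinetics import fit_double_exponential, find_decay_window

    ss = simulate_sweepset(wt_clean, deact_proto, 0, 0, cap_amp_factor=0.0)
    t, cur = slice_epoch(ss, deact_proto.sweep_variable)
    taus = []
    for v in (-160.0, -130.0, -100.0):
        trace = cur[ss.sweep_index(v)]
        f = fit_double_exponential(t, trace, find_decay_window(t, trace))
        taus.append(f.tau_fast)
    assert taus[0] < taus[1] < taus[2]


def test_voltage_dependent_amplitude_variant(deact_proto):
    """With the linear amplitude variant the fast fraction grows at
    negative voltages (and shrinks at depolarized ones)."""
    from deactkit.preprocess import slice_epoch
    from deactkit.tail_kinetics import fit_double_exponential, find_decay_window

    m = cohorts.paper_model(
        "WT", noise_sd_frac=0.0, oocyte_cv=0.0, g_leak=0.0,
        amp_fast_frac_ref=0.8, amp_fast_slope_per_mv=-0.003,
    )
    ss = simulate_sweepset(m, deact_proto, 0, 0, cap_amp_factor=0.0)
    t, cur = slice_epoch(ss, deact_proto.sweep_variable)
    rel = {}
    for v in (-160.0, -60.0):
        trace = cur[ss.sweep_index(v)]
        f = fit_double_exponential(t, trace, find_decay_window(t, trace))
        rel[v] = f.rel_amp_fast
    assert rel[-160.0] > rel[-60.0]


class TestMakeCohort:
    def test_cohort_counts_and_unique_ids(self, wt_model):
        ggs = cohorts.paper_model("GGS")
        cohort = make_cohort([wt_model, ggs], 3, seed=0)
        recs = [r for group in cohort.values() for r in group]
        assert len(recs) == 6  # 12 sweep sets, 2 protocols each
        ids = [r.oocyte_id for r in recs]
        assert len(set(ids)) == 6
        for r in recs:
            assert r.activation.protocol.name == "activation"
            assert r.deactivation.protocol.name == "deactivation"

    def test_zero_variability_cohort_is_homogeneous(self):
        m = cohorts.paper_model("WT", oocyte_cv=0.0, noise_sd_frac=0.0)
        cohort = make_cohort([m], 3, seed=0)
        base = cohort["WT"][0]
        for rec in cohort["WT"][1:]:
            assert np.array_equal(rec.activation.currents, base.activation.currents)
            assert np.array_equal(
                rec.deactivation.currents, base.deactivation.currents
            )

    def test_shared_jitter_between_protocols(self, wt_model):
        cohort = make_cohort([wt_model], 2, seed=5)
        for rec in cohort["WT"]:
            assert rec.activation.true_model == rec.deactivation.true_model

    def test_invalid_replicate_count(self, wt_model):
        with pytest.raises(ValueError):
            make_cohort([wt_model], 0, seed=0)
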