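"""Synthetic two-electrode voltage-clamp recordings.

The generator emulates the statistical structure of oocyte recordings of
hERG-type channels: within each constant-voltage epoch the channel open
fraction relaxes from its previous value toward the Boltzmann steady
state; repolarizing relaxations are bi-exponential with voltage-dependent
time constants (single e-fold law anchored at -120 mV) while activating
relaxations follow a single fixed time constant.  The measured current is
the ionic current ``g_max * p * (V - E_rev)`` plus a linear leak referenced
to the holding potential, a capacitive transient at every step edge, and
additive Gaussian noise.  Between-oocyte variability is multiplicative
lognormal jitter on the kinetic anchors and the activation midpoint.

All randomness is reproducible from ``(seed, oocyte_id)``; noise streams
for different protocols are decorrelated through the protocol name.

The noise fraction is defined relative to the local signal: within each
epoch the sample noise has sd = noise_sd_frac times that epoch's peak
ionic current, so "1% noise" means a signal-to-noise ratio of 100 on
every analyzed segment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .models import (
    Epoch,
    GatingModel,
    LEAK_LINEAR_RANGE,
    ProtocolRangeError,
    SweepSet,
    VoltageProtocol,
)

__all__ = [
    "activation_protocol",
    "deactivation_protocol",
    "simulate_sweepset",
    "make_cohort",
    "OocyteRecording",
]

#: Capacitive-transient decay time constant (ms).
CAP_TAU = 1.0
#: Capacitive-transient amplitude, relative to the peak ionic current of
#: the epoch that follows the step edge.
CAP_AMP_FACTOR = 5.0


def activation_protocol(
    *,
    holding: float = -90.0,
    v_start: float = -70.0,
    v_stop: float = 40.0,  # stays inside the linear-leak validity range
    v_step: float = 10.0,
    step_ms: float = 4000.0,
    tail_level: float = -70.0,
    tail_ms: float = 1000.0,
    sample_interval: float = 1.0,
) -> VoltageProtocol:
    """Isochronal activation protocol: 4-s steps, tail at -70 mV."""
    levels = tuple(np.arange(v_start, v_stop + 0.5 * abs(v_step), v_step))
    epochs = (
        Epoch(holding, 100.0),
        Epoch(holding + 20.0, 100.0),  # leak-check step
        Epoch(holding, 50.0),
        Epoch(0.0, step_ms),  # variable depolarizing step
        Epoch(tail_level, tail_ms),
    )
    return VoltageProtocol(
        name="activation",
        holding=holding,
        epochs=epochs,
        sweep_variable=3,
        sweep_levels=levels,
        sample_interval=sample_interval,
    )


def deactivation_protocol(
    *,
    holding: float = -90.0,
    v_start: float = -50.0,
    v_stop: float = -160.0,
    v_step: float = -10.0,
    depol_level: float = 40.0,
    depol_ms: float = 1000.0,
    tail_ms: float = 2000.0,  # several slow time constants, for stable fits
    sample_interval: float = 0.5,
) -> VoltageProtocol:
    """Deactivation protocol: 1-s step to +40 mV, repolarizing tails."""
    levels = tuple(np.arange(v_start, v_stop - 0.5 * abs(v_step), v_step))
    epochs = (
        Epoch(holding, 100.0),
        Epoch(holding + 20.0, 100.0),  # leak-check step
        Epoch(holding, 50.0),
        Epoch(depol_level, depol_ms),
        Epoch(0.0, tail_ms),  # variable repolarization level
    )
    return VoltageProtocol(
        name="deactivation",
        holding=holding,
        epochs=epochs,
        sweep_variable=4,
        sweep_levels=levels,
        sample_interval=sample_interval,
    )


def _validate_range(protocol: VoltageProtocol) -> None:
    lo, hi = LEAK_LINEAR_RANGE
    bad = [v for v in protocol.all_levels() if not lo <= v <= hi]
    if bad:
        raise ProtocolRangeError(
            f"protocol '{protocol.name}' steps to {sorted(set(bad))} mV, "
            f"outside the linear-leak range {lo}..{hi} mV"
        )


def _noise_stream(seed: int, oocyte_id: int, protocol_name: str) -> np.random.Generator:
    tag = zlib.crc32(protocol_name.encode()) % (2**31 - 1)
    return np.random.default_rng([int(seed), int(oocyte_id), int(tag)])


def simulate_sweepset(
    model: GatingModel,
    protocol: VoltageProtocol,
    oocyte_id: int = 0,
    seed: int = 0,
    *,
    noise_sd_frac: float | None = None,
    cap_amp_factor: float = CAP_AMP_FACTOR,
    cap_tau: float = CAP_TAU,
) -> SweepSet:
    """Simulate one oocyte's recording of one protocol.

    Parameters
    ----------
    noise_sd_frac
        Overrides the model's sample-noise level for this protocol (e.g.
        1% for deactivation, 2% for activation recordings).

    Returns a leak-contaminated, noisy :class:`SweepSet` whose
    ``ideal_currents`` hold the noiseless, leak-free ionic component and
    whose ``true_model`` is the jittered per-oocyte parameter set.
    """
    _validate_range(protocol)
    m = model.jittered(seed, oocyte_id)
    nf = model.noise_sd_frac if noise_sd_frac is None else float(noise_sd_frac)

    dt = protocol.sample_interval
    time = protocol.time()
    slices = protocol.epoch_slices()
    durations = protocol.durations
    n_sweeps = len(protocol.sweep_levels)

    ionic = np.zeros((n_sweeps, time.size))
    total = np.zeros_like(ionic)
    rng = _noise_stream(seed, oocyte_id, protocol.name)

    for s in range(n_sweeps):
        levels = protocol.epoch_levels(s)
        p = float(m.p_inf(protocol.holding))
        for k, (lvl, sl) in enumerate(zip(levels, slices)):
            t_rel = time[sl] - (time[sl.start] if sl.start < time.size else 0.0)
            p_inf = float(m.p_inf(lvl))
            if p_inf >= p:  # activating relaxation
                decay = np.exp(-t_rel / m.tau_act)
                end = np.exp(-durations[k] / m.tau_act)
            else:  # deactivating relaxation: bi-exponential
                tf = float(m.tau_fast(lvl))
                ts = float(m.tau_slow(lvl))
                a = m.amp_fast_frac(lvl)
                decay = a * np.exp(-t_rel / tf) + (1 - a) * np.exp(-t_rel / ts)
                end = a * np.exp(-durations[k] / tf) + (1 - a) * np.exp(
                    -durations[k] / ts
                )
            traj = p_inf + (p - p_inf) * decay
            p = p_inf + (p - p_inf) * float(end)
            ionic[s, sl] = m.g_max * traj * (lvl - m.e_rev) / 1000.0
            total[s, sl] = ionic[s, sl] + m.g_leak * (lvl - protocol.holding) / 1000.0

        # capacitive transients at every step edge, decaying into the
        # following epoch, scaled to that epoch's peak ionic current
        for k in range(1, len(levels)):
            dv = levels[k] - levels[k - 1]
            if dv == 0.0:
                continue
            sl = slices[k]
            peak = float(np.max(np.abs(ionic[s, sl]))) if sl.stop > sl.start else 0.0
            amp = cap_amp_factor * peak * np.sign(dv)
            t_rel = time[sl] - time[sl.start]
            total[s, sl] += amp * np.exp(-t_rel / cap_tau)

        if nf > 0:
            # noise scaled per epoch to that epoch's own peak ionic
            # current, so every analyzed segment has SNR = 1/noise_frac
            for sl in slices:
                sd = nf * float(np.max(np.abs(ionic[s, sl]))) if sl.stop > sl.start else 0.0
                if sd > 0:
                    total[s, sl] += rng.normal(0.0, sd, size=sl.stop - sl.start)

    return SweepSet(
        protocol=protocol,
        time=time,
        currents=total,
        construct_label=model.construct_label,
        oocyte_id=oocyte_id,
        rng_seed=seed,
        is_leak_subtracted=False,
        ideal_currents=ionic,
        true_model=m,
    )


@dataclass
class OocyteRecording:
    """Both protocols recorded from one (virtual) oocyte."""

    construct_label: str
    oocyte_id: int
    activation: SweepSet
    deactivation: SweepSet


def make_cohort(
    models: list[GatingModel] | GatingModel,
    n_oocytes: int | dict[str, int],
    seed: int = 0,
    *,
    act_protocol: VoltageProtocol | None = None,
    deact_protocol: VoltageProtocol | None = None,
    act_noise_sd_frac: float | None = None,
    deact_noise_sd_frac: float | None = None,
) -> dict[str, list[OocyteRecording]]:
    """Simulate an n-replicate cohort for each construct.

    Each oocyte records both the activation and the deactivation protocol
    with shared jittered parameters.  Oocyte ids are unique across the
    whole cohort so different constructs draw independent jitter.  The
    result is deterministic under ``seed``.
    """
    if isinstance(models, GatingModel):
        models = [models]
    act_protocol = act_protocol or activation_protocol()
    deact_protocol = deact_protocol or deactivation_protocol()

    cohort: dict[str, list[OocyteRecording]] = {}
    next_id = 0
    for model in models:
        n = n_oocytes[model.construct_label] if isinstance(n_oocytes, dict) else n_oocytes
        if n < 1:
            raise ValueError("n_oocytes must be >= 1")
        recs = []
        for _ in range(n):
            oid = next_id
            next_id += 1
            act = simulate_sweepset(
                model, act_protocol, oid, seed, noise_sd_frac=act_noise_sd_frac
            )
            deact = simulate_sweepset(
                model, deact_protocol, oid, seed, noise_sd_frac=deact_noise_sd_frac
            )
            recs.append(
                OocyteRecording(model.construct_label, oid, act, deact)
            )
        cohort[model.construct_label] = recs
    return cohort
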