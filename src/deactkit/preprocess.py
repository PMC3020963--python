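"""Off-line linear leak subtraction and epoch utilities.

Every sweep starts with a +20 mV step from the holding potential.  Because
the channels carry essentially no current there (the driving force at
holding is ~0 and the open probability is vanishing), the current change
across that step measures the passive leak conductance.  Leak is assumed
linear over -160..+40 mV and to reverse at the holding potential; the
reversal offset is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import SweepSet

__all__ = [
    "LeakEstimate",
    "LeakCheckMissingError",
    "AlreadySubtractedError",
    "estimate_leak",
    "subtract_leak",
    "slice_epoch",
]


class LeakCheckMissingError(ValueError):
    """The protocol has no epoch at the leak-check level."""


class AlreadySubtractedError(ValueError):
    """Leak subtraction was applied twice to the same sweep set."""


@dataclass(frozen=True)
class LeakEstimate:
    """Passive leak parameters estimated from the +20 mV check step."""

    g_leak_hat: float  # uS
    baseline_at_holding: float  # uA
    source_step: tuple[float, float]  # (from mV, to mV)
    negative_conductance: bool = False  # warning flag, not an error


def _plateau_mean(currents: np.ndarray, sl: slice, min_samples: int) -> float:
    """Mean over the trailing 50% of an epoch (all sweeps pooled)."""
    n = sl.stop - sl.start
    tail = slice(sl.start + n // 2, sl.stop)
    if tail.stop - tail.start < min_samples:
        raise ValueError(
            f"plateau region has {tail.stop - tail.start} samples; "
            f"need at least {min_samples} after transient settling"
        )
    return float(np.mean(currents[:, tail]))


def _find_check_epochs(sweep: SweepSet) -> tuple[int, int]:
    """(holding epoch, check epoch) indices used for the leak estimate."""
    proto = sweep.protocol
    check = proto.check_level
    check_idx = None
    for k, ep in enumerate(proto.epochs):
        if k != proto.sweep_variable and np.isclose(ep.level, check):
            check_idx = k
            break
    if check_idx is None:
        raise LeakCheckMissingError(
            f"protocol '{proto.name}' has no epoch at the leak-check "
            f"level {check} mV"
        )
    base_idx = None
    for k in range(check_idx - 1, -1, -1):
        if k != proto.sweep_variable and np.isclose(proto.epochs[k].level, proto.holding):
            base_idx = k
            break
    if base_idx is None:
        raise LeakCheckMissingError(
            "no holding-level epoch precedes the leak-check step"
        )
    return base_idx, check_idx


def estimate_leak(sweep: SweepSet, min_samples: int = 10) -> LeakEstimate:
    """Estimate the linear leak from the +20 mV check step.

    The plateau current is averaged over the trailing half of the holding
    and check epochs (skipping capacitive transients) and pooled across
    sweeps; ``g_leak_hat = dI/dV`` over the 20 mV step.
    """
    proto = sweep.protocol
    base_idx, check_idx = _find_check_epochs(sweep)
    slices = proto.epoch_slices()
    i_hold = _plateau_mean(sweep.currents, slices[base_idx], min_samples)
    i_check = _plateau_mean(sweep.currents, slices[check_idx], min_samples)
    dv = proto.check_level - proto.holding
    g = (i_check - i_hold) / dv * 1000.0  # uA/mV -> uS
    return LeakEstimate(
        g_leak_hat=g,
        baseline_at_holding=i_hold,
        source_step=(proto.holding, proto.check_level),
        negative_conductance=bool(g < 0),
    )


def subtract_leak(
    sweep: SweepSet,
    leak: LeakEstimate | None = None,
    leak_reversal: float | None = None,
) -> SweepSet:
    """Subtract baseline plus the linear leak from every sample.

    ``leak_reversal`` defaults to the holding potential (the leak model
    is ``g_leak * (V - V_rev)``); pass a different value to move the leak
    reversal.  Returns a new :class:`SweepSet` with the flag set.
    """
    if sweep.is_leak_subtracted:
        raise AlreadySubtractedError("sweep set is already leak-subtracted")
    if leak is None:
        leak = estimate_leak(sweep)
    v_rev = sweep.protocol.holding if leak_reversal is None else leak_reversal
    v = sweep.protocol.voltage_matrix()
    predicted = leak.baseline_at_holding + leak.g_leak_hat * (v - v_rev) / 1000.0
    return replace(
        sweep,
        currents=sweep.currents - predicted,
        is_leak_subtracted=True,
    )


def slice_epoch(sweep: SweepSet, epoch_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Time (re-zeroed at epoch start) and traces of one epoch."""
    slices = sweep.protocol.epoch_slices()
    if not 0 <= epoch_index < len(slices):
        raise IndexError(
            f"epoch index {epoch_index} out of range 0..{len(slices) - 1}"
        )
    sl = slices[epoch_index]
    t = sweep.time[sl] - sweep.time[sl.start]
    return t, sweep.currents[:, sl]
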