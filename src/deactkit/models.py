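"""Core domain records: gating model, voltage protocol and sweep set.

A :class:`GatingModel` is the generative description of one channel
construct (wild type or mutant): its steady-state activation (Boltzmann
midpoint/slope, equivalently chemical work and gating charge), its
deactivation kinetics (fast and slow tail time constants anchored at a
reference voltage with a shared e-fold voltage dependence), passive
properties of the oocyte (maximal conductance, K+ reversal, linear leak)
and the statistical structure of the recordings (sample noise, oocyte-to-
oocyte variability).

A :class:`VoltageProtocol` is an ordered list of constant-voltage epochs;
one epoch's level varies across sweeps.  A :class:`SweepSet` is the raw
unit every analysis stage consumes: a time base plus one current trace per
sweep.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C

__all__ = [
    "Epoch",
    "VoltageProtocol",
    "GatingModel",
    "SweepSet",
    "ProtocolRangeError",
]

#: Voltage range (mV) over which the leak is assumed linear; protocols
#: stepping outside this range are rejected by the simulator.
LEAK_LINEAR_RANGE = (-160.0, 40.0)


class ProtocolRangeError(ValueError):
    """A protocol steps outside the linear-leak validity range."""


@dataclass(frozen=True)
class Epoch:
    """One constant-voltage segment of a sweep."""

    level: float  # mV; for the sweep-variable epoch this is a placeholder
    duration: float  # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")


@dataclass(frozen=True)
class VoltageProtocol:
    """Voltage-step protocol: per-sweep epochs with one variable level."""

    name: str
    holding: float  # mV
    epochs: tuple[Epoch, ...]
    sweep_variable: int  # index of the epoch whose level varies per sweep
    sweep_levels: tuple[float, ...]  # mV, one per sweep
    sample_interval: float  # ms
    leak_check_level: float | None = None  # defaults to holding + 20 mV

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if not self.sweep_levels:
            raise ValueError("sweep_levels must be nonempty")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not (0 <= self.sweep_variable < len(self.epochs)):
            raise ValueError("sweep_variable out of range")

    @property
    def check_level(self) -> float:
        """Voltage of the leak-check step (holding + 20 mV by default)."""
        if self.leak_check_level is not None:
            return self.leak_check_level
        return self.holding + 20.0

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.epochs], dtype=float)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.sample_interval))

    def time(self) -> np.ndarray:
        """Uniform time base (ms), starting at 0."""
        return np.arange(self.n_samples) * self.sample_interval

    def epoch_slices(self) -> list[slice]:
        """Sample index ranges of each epoch."""
        edges = np.concatenate([[0.0], np.cumsum(self.durations)])
        idx = np.round(edges / self.sample_interval).astype(int)
        idx[-1] = min(idx[-1], self.n_samples)
        return [slice(int(a), int(b)) for a, b in zip(idx[:-1], idx[1:])]

    def epoch_levels(self, sweep_index: int) -> tuple[float, ...]:
        """Epoch voltages for one sweep, with the variable level filled in."""
        levels = [e.level for e in self.epochs]
        levels[self.sweep_variable] = self.sweep_levels[sweep_index]
        return tuple(levels)

    def all_levels(self) -> list[float]:
        levels = [self.holding, self.check_level]
        levels += [e.level for i, e in enumerate(self.epochs) if i != self.sweep_variable]
        levels += list(self.sweep_levels)
        return levels

    def voltage_matrix(self) -> np.ndarray:
        """Command voltage per (sweep, sample), in mV."""
        out = np.empty((len(self.sweep_levels), self.n_samples))
        slices = self.epoch_slices()
        for s in range(len(self.sweep_levels)):
            for lvl, sl in zip(self.epoch_levels(s), slices):
                out[s, sl] = lvl
        return out


def _check_identity(value: float, expected: float, what: str) -> None:
    scale = max(1.0, abs(expected))
    if abs(value - expected) > 1e-9 * scale:
        raise ValueError(
            f"inconsistent gating parameterization: {what}={value!r} "
            f"but the energetic parameters imply {expected!r}"
        )


@dataclass(frozen=True)
class GatingModel:
    """Generative parameters for one channel construct.

    The activation parameters are stored redundantly in both the voltage
    form (``v_half``, ``slope_k``) and the energetic form (``dg0``, ``z_g``);
    the constructor enforces the thermodynamic identities
    ``v_half = dg0/(z_g F)`` and ``slope_k = RT/(z_g F)`` to 1e-9 relative.
    Use the ``from_*`` classmethods, which derive one pair from the other.
    """

    construct_label: str
    v_half: float  # mV
    slope_k: float  # mV
    dg0: float  # kJ/mol
    z_g: float  # elementary charges
    tau_fast_ref: float  # ms, fast tail time constant at tau_ref_voltage
    tau_slow_ref: float  # ms, slow tail time constant at tau_ref_voltage
    tau_voltage_efold: float  # mV per e-fold change of both time constants
    amp_fast_frac_ref: float = 0.85  # fast-component weight at tau_ref_voltage
    amp_fast_slope_per_mv: float = 0.0  # optional linear voltage dependence
    tau_act: float = 150.0  # ms, activation relaxation time constant
    g_max: float = 30.0  # uS
    e_rev: float = -90.0  # mV, K+ reversal
    g_leak: float = 0.3  # uS
    noise_sd_frac: float = 0.01  # Gaussian noise sd as fraction of peak ionic
    oocyte_cv: float = 0.10  # CV of between-oocyte lognormal jitter
    temperature: float = C.T_ROOM  # K
    tau_ref_voltage: float = -120.0  # mV, anchor of the tau(V) law

    def __post_init__(self):
        if self.slope_k <= 0:
            raise ValueError("slope_k must be positive")
        if not self.tau_fast_ref < self.tau_slow_ref:
            raise ValueError("tau_fast_ref must be smaller than tau_slow_ref")
        if not 0.0 <= self.amp_fast_frac_ref <= 1.0:
            raise ValueError("amp_fast_frac_ref must lie in [0, 1]")
        if self.tau_act <= 0:
            raise ValueError("tau_act must be positive")
        _check_identity(
            self.v_half, C.vhalf_from_dg0(self.dg0, self.z_g), "v_half"
        )
        _check_identity(
            self.slope_k, C.slope_from_zg(self.z_g, self.temperature), "slope_k"
        )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_voltage(cls, construct_label: str, *, v_half: float, slope_k: float,
                     temperature: float = C.T_ROOM, **kw) -> "GatingModel":
        z_g = C.zg_from_slope(slope_k, temperature)
        return cls(construct_label, v_half, slope_k,
                   C.dg0_from_vhalf(v_half, z_g), z_g,
                   temperature=temperature, **kw)

    @classmethod
    def from_energy(cls, construct_label: str, *, dg0: float, z_g: float,
                    temperature: float = C.T_ROOM, **kw) -> "GatingModel":
        return cls(construct_label, C.vhalf_from_dg0(dg0, z_g),
                   C.slope_from_zg(z_g, temperature), dg0, z_g,
                   temperature=temperature, **kw)

    @classmethod
    def from_midpoint_energy(cls, construct_label: str, *, v_half: float,
                             dg0: float, temperature: float = C.T_ROOM,
                             **kw) -> "GatingModel":
        """Build from the two printed quantities V0.5 and dG0; z_g follows."""
        z_g = dg0 / (C.FARADAY * v_half / 1000.0)
        return cls(construct_label, v_half, C.slope_from_zg(z_g, temperature),
                   dg0, z_g, temperature=temperature, **kw)

    # -- generative laws ----------------------------------------------
    def p_inf(self, v_mv):
        """Steady-state (Boltzmann) open fraction at a voltage."""
        return C.boltzmann_open_fraction(v_mv, self.v_half, self.slope_k)

    def tau_fast(self, v_mv):
        """Fast deactivation time constant (ms) at a voltage."""
        return self.tau_fast_ref * np.exp(
            (np.asarray(v_mv, dtype=float) - self.tau_ref_voltage)
            / self.tau_voltage_efold
        )

    def tau_slow(self, v_mv):
        """Slow deactivation time constant (ms) at a voltage."""
        return self.tau_slow_ref * np.exp(
            (np.asarray(v_mv, dtype=float) - self.tau_ref_voltage)
            / self.tau_voltage_efold
        )

    def amp_fast_frac(self, v_mv) -> float:
        """Relative weight of the fast component at a voltage."""
        a = self.amp_fast_frac_ref + self.amp_fast_slope_per_mv * (
            float(v_mv) - self.tau_ref_voltage
        )
        return float(np.clip(a, 0.0, 1.0))

    # -- between-oocyte variability -----------------------------------
    def jittered(self, seed: int, oocyte_id: int) -> "GatingModel":
        """Per-oocyte parameter draw, deterministic in (seed, oocyte_id).

        The midpoint, both tau anchors and the fast-component weight are
        multiplied by independent lognormal factors of unit mean and
        coefficient of variation ``oocyte_cv``; the slope factor is left
        untouched, so ``dg0`` co-varies with ``v_half`` at fixed ``z_g``.
        """
        if self.oocyte_cv <= 0:
            return self
        rng = np.random.default_rng([int(seed), int(oocyte_id)])
        sigma = math.sqrt(math.log1p(self.oocyte_cv**2))
        f = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=4)
        v_half = self.v_half * f[0]
        tau_f = self.tau_fast_ref * f[1]
        tau_s = self.tau_slow_ref * f[2]
        if tau_s <= tau_f:  # pathological draw; keep ordering
            tau_f, tau_s = min(tau_f, tau_s) * 0.999, max(tau_f, tau_s)
        amp = float(np.clip(self.amp_fast_frac_ref * f[3], 0.0, 1.0))
        return replace(
            self,
            v_half=v_half,
            dg0=C.dg0_from_vhalf(v_half, self.z_g),
            tau_fast_ref=tau_f,
            tau_slow_ref=tau_s,
            amp_fast_frac_ref=amp,
            oocyte_cv=0.0,
        )


@dataclass
class SweepSet:
    """One recording: time base plus per-sweep current traces (uA).

    ``ideal_currents`` and ``true_model`` carry generator ground truth
    (the noise-, leak- and capacitance-free ionic component and the
    jittered per-oocyte parameters); they are absent on imported data and
    are used only as oracles in validation.
    """

    protocol: VoltageProtocol
    time: np.ndarray  # ms
    currents: np.ndarray  # (n_sweeps, n_samples) uA
    construct_label: str
    oocyte_id: int
    rng_seed: int
    is_leak_subtracted: bool = False
    ideal_currents: np.ndarray | None = None
    true_model: GatingModel | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.ndim != 2:
            raise ValueError("currents must be a (sweep, sample) matrix")
        if self.currents.shape[0] != len(self.protocol.sweep_levels):
            raise ValueError("one current trace per sweep level is required")
        if self.currents.shape[1] != self.time.size:
            raise ValueError("time base and traces disagree in length")
        dt = np.diff(self.time)
        if self.time.size > 1 and not (
            np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12)
        ):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def n_sweeps(self) -> int:
        return self.currents.shape[0]

    def sweep_index(self, level: float) -> int:
        """Index of the sweep whose variable epoch sits at ``level`` mV."""
        levels = np.asarray(self.protocol.sweep_levels)
        hits = np.nonzero(np.isclose(levels, level))[0]
        if hits.size == 0:
            raise KeyError(f"no sweep at {level} mV")
        return int(hits[0])
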