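"""Electrochemical driving-force conversion for deactivation rates.

Mutations that shift the activation curve change the energetic bias on the
gate at any fixed repolarization voltage, so raw tau(V) comparisons between
constructs conflate kinetics with energetics.  The total electrochemical
driving force at membrane potential E is

    DF = -(dG0 - z_g * E * F)        [kJ/mol, E in volts]

and constructs are compared at an equivalent driving force (by convention
-30 kJ/mol).  tau at the target is obtained by linear interpolation of
log(tau) against DF between the bracketing measured points (tau is positive
and near-exponential in voltage, making log-tau near-linear in DF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .tail_kinetics import TailFit

__all__ = [
    "DrivingForceCurve",
    "to_driving_force",
    "build_curve",
    "tau_at_driving_force",
]

#: Comparison point used throughout (kJ/mol).
DEFAULT_TARGET_DF = -30.0


def to_driving_force(e_mv, dg0: float, z_g: float):
    """Electrochemical driving force (kJ/mol) at membrane potential(s) in mV."""
    e = np.asarray(e_mv, dtype=float)
    return -(dg0 - z_g * C.FARADAY * e / 1000.0)


def voltage_at_driving_force(df: float, dg0: float, z_g: float) -> float:
    """Membrane potential (mV) at which the driving force equals ``df``."""
    return 1000.0 * (dg0 + df) / (z_g * C.FARADAY)


@dataclass
class DrivingForceCurve:
    """Per-construct tau(DF) relation from tail fits plus activation energetics."""

    construct_label: str
    df: np.ndarray  # kJ/mol, ascending
    tau_fast: np.ndarray  # ms
    tau_slow: np.ndarray  # ms (NaN where a single component was fitted)
    voltages: np.ndarray  # mV, aligned with df
    dg0: float
    z_g: float


def build_curve(
    tail_fits: list[TailFit],
    dg0: float,
    z_g: float,
    construct_label: str = "",
    v_min: float = -160.0,
    v_max: float = -60.0,
) -> DrivingForceCurve:
    """Convert fitted tail time constants to a tau(DF) curve.

    Only usable fits enter the curve: within ``v_min..v_max`` (the
    conversion range), converged, with a finite fast time constant, an
    unflagged decay window, and a tail amplitude of at least 2% of the
    largest tail in the set.  The amplitude guard drops sweeps recorded
    near the K+ reversal potential, where there is no measurable tail
    current and a "fit" is meaningless.  Points are sorted by driving
    force.
    """
    cands = [
        f
        for f in tail_fits
        if f.voltage is not None
        and v_min <= f.voltage <= v_max
        and np.isfinite(f.tau_fast)
        and f.converged
        and not f.fit_window.flagged
    ]
    if cands:
        amps = np.array([abs(f.a_fast) + abs(f.a_slow) for f in cands])
        rows = [f for f, a in zip(cands, amps) if a >= 0.02 * amps.max()]
    else:
        rows = []
    if not rows:
        raise ValueError("no usable tail fits in the conversion range")
    v = np.array([f.voltage for f in rows], dtype=float)
    df = to_driving_force(v, dg0, z_g)
    order = np.argsort(df)
    return DrivingForceCurve(
        construct_label=construct_label,
        df=df[order],
        tau_fast=np.array([f.tau_fast for f in rows])[order],
        tau_slow=np.array([f.tau_slow for f in rows])[order],
        voltages=v[order],
        dg0=dg0,
        z_g=z_g,
    )


def tau_at_driving_force(
    curve: DrivingForceCurve,
    target_df: float = DEFAULT_TARGET_DF,
    log_tau: bool = True,
    allow_extrapolation: bool = False,
) -> float:
    """tau_fast (ms) at a target driving force, by interpolation.

    By default log(tau) is interpolated linearly in DF between the two
    bracketing points; a target outside the measured span raises unless
    extrapolation is explicitly allowed (then the edge segment is extended).
    """
    df = curve.df
    tau = curve.tau_fast
    ok = np.isfinite(tau) & (tau > 0)
    df, tau = df[ok], tau[ok]
    if df.size < 2:
        raise ValueError("need at least two finite tau points to interpolate")
    if not allow_extrapolation and not (df.min() <= target_df <= df.max()):
        raise ValueError(
            f"target {target_df} kJ/mol outside the measured span "
            f"[{df.min():.2f}, {df.max():.2f}]; pass allow_extrapolation=True "
            "to extend the edge segment"
        )
    y = np.log(tau) if log_tau else tau
    if allow_extrapolation and not (df.min() <= target_df <= df.max()):
        # linear extension of the nearest edge segment
        if target_df < df.min():
            i0, i1 = 0, 1
        else:
            i0, i1 = -2, -1
        slope = (y[i1] - y[i0]) / (df[i1] - df[i0])
        val = y[i1] + slope * (target_df - df[i1])
    else:
        val = float(np.interp(target_df, df, y))
    return float(math.exp(val)) if log_tau else float(val)
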