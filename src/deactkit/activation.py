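"""Isochronal activation curves and Boltzmann fits.

The normalized peak tail current recorded at a fixed voltage after a long
depolarizing step estimates the relative conductance ``g/g_max`` at the
preceding step voltage.  The curve is fitted with a two-state Boltzmann
in either the voltage parameterization (midpoint ``V0.5``, slope ``k``) or
the energetic parameterization (``dG0``, ``z_g``); the two are the same
model and every fit is reported both ways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from . import constants as C
from .models import SweepSet
from .tail_kinetics import DEFAULT_BLANK_MS

__all__ = [
    "ActivationFit",
    "BoltzmannActivation",
    "build_activation_curve",
    "fit_boltzmann",
    "fit_activation",
]


@dataclass
class ActivationFit:
    """Boltzmann fit of one oocyte's activation curve, both parameterizations."""

    v_half_hat: float  # mV
    k_hat: float  # mV
    dg0_hat: float  # kJ/mol
    z_g_hat: float
    i_max: float  # uA (peak tail used for normalization)
    points: list[tuple[float, float]]  # (V_t mV, normalized tail)
    rss: float
    converged: bool


def build_activation_curve(
    sweepset: SweepSet,
    blank_ms: float = DEFAULT_BLANK_MS,
    method: str = "window_mean",
    avg_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized peak-tail activation curve from an activation sweep set.

    Returns ``(test_voltages, g_over_gmax, i_max)``, normalized to the
    maximum across sweeps.  With ``method="window_mean"`` (default) the
    tail amplitude is the mean current over ``avg_ms`` after the blank
    period: because the tail kinetics at the fixed tail voltage are the
    same for every sweep, this is proportional to the instantaneous tail
    amplitude and, unlike a raw extremum of a noisy trace, carries no
    max-statistic bias.  ``method="extremum"`` takes the signed extremum
    after the blank period instead.
    """
    if not sweepset.is_leak_subtracted:
        raise ValueError("build_activation_curve requires leak-subtracted data")
    if method not in ("window_mean", "extremum"):
        raise ValueError("method must be 'window_mean' or 'extremum'")
    proto = sweepset.protocol
    tail_sl = proto.epoch_slices()[-1]
    t = sweepset.time[tail_sl] - sweepset.time[tail_sl.start]
    i0 = int(np.searchsorted(t, blank_ms))
    i1 = int(np.searchsorted(t, blank_ms + avg_ms))
    peaks = np.empty(sweepset.n_sweeps)
    for s in range(sweepset.n_sweeps):
        seg = sweepset.currents[s, tail_sl][i0:]
        if method == "window_mean":
            peaks[s] = float(np.mean(sweepset.currents[s, tail_sl][i0:i1]))
        else:
            peaks[s] = seg[int(np.argmax(np.abs(seg)))]
    i_max = float(peaks.max())
    if i_max <= 0:
        raise ValueError("non-positive maximal tail current; cannot normalize")
    v = np.asarray(proto.sweep_levels, dtype=float)
    order = np.argsort(v)
    return v[order], peaks[order] / i_max, i_max


class BoltzmannActivation(BaseEstimator):
    """Two-state Boltzmann activation model, scikit-learn style.

    Parameters
    ----------
    parameterization : {"voltage", "energy"}
        Fit in (V0.5, k) or directly in (dG0, z_g); the parameterizations
        are equivalent and the complementary pair is always derived.
    fix_amplitude : bool
        If True, pin the saturating amplitude at 1 (the data are already
        normalized to the peak tail current).  The default co-estimates a
        free amplitude: normalizing by the largest *noisy* point leaves a
        small multiplicative error that a pinned amplitude converts into
        a systematic slope bias, whereas a free amplitude absorbs it.
    temperature : float
        Absolute temperature (K) used for the energetic conversion.

    Fitted attributes: ``v_half_``, ``k_``, ``dg0_``, ``z_g_``,
    ``amplitude_``, ``rss_``, ``converged_``.
    """

    def __init__(
        self,
        parameterization: str = "voltage",
        fix_amplitude: bool = False,
        temperature: float = C.T_ROOM,
    ):
        self.parameterization = parameterization
        self.fix_amplitude = fix_amplitude
        self.temperature = temperature

    def fit(self, v, g):
        v = np.asarray(v, dtype=float).ravel()
        g = np.asarray(g, dtype=float).ravel()
        if v.size != g.size or v.size < 5:
            raise ValueError("need >= 5 (voltage, conductance) points")
        rt = C.thermal_energy(self.temperature)
        if self.parameterization not in ("voltage", "energy"):
            raise ValueError("parameterization must be 'voltage' or 'energy'")

        # initial guesses from the half-crossing of the curve
        v0 = float(v[np.argmin(np.abs(g - 0.5 * g.max()))])
        if self.parameterization == "voltage":
            if self.fix_amplitude:
                f = lambda x, vh, k: 1.0 / (1.0 + np.exp((vh - x) / k))
                p0 = [v0, 8.0]
                bounds = ([-np.inf, 1e-6], [np.inf, np.inf])
            else:
                f = lambda x, vh, k, a: a / (1.0 + np.exp((vh - x) / k))
                p0 = [v0, 8.0, float(g.max())]
                bounds = ([-np.inf, 1e-6, 1e-9], [np.inf, np.inf, np.inf])
        else:
            # g = A / (1 + exp((dG0 - z_g*F*E)/RT)), E in volts
            if self.fix_amplitude:
                f = lambda x, dg0, zg: 1.0 / (
                    1.0 + np.exp((dg0 - zg * C.FARADAY * x / 1000.0) / rt)
                )
                p0 = [3.0 * C.FARADAY * v0 / 1000.0, 3.0]
                bounds = ([-np.inf, 1e-6], [np.inf, np.inf])
            else:
                f = lambda x, dg0, zg, a: a / (
                    1.0 + np.exp((dg0 - zg * C.FARADAY * x / 1000.0) / rt)
                )
                p0 = [3.0 * C.FARADAY * v0 / 1000.0, 3.0, float(g.max())]
                bounds = ([-np.inf, 1e-6, 1e-9], [np.inf, np.inf, np.inf])

        try:
            popt, _ = curve_fit(
                f, v, g, p0=p0, bounds=bounds, ftol=1e-14, xtol=1e-14,
                gtol=1e-14, maxfev=20000,
            )
            ok = True
        except Exception:
            popt = [math.nan] * len(p0)
            ok = False

        if self.parameterization == "voltage":
            self.v_half_ = float(popt[0])
            self.k_ = float(popt[1])
            if ok:
                self.z_g_ = C.zg_from_slope(self.k_, self.temperature)
                self.dg0_ = C.dg0_from_vhalf(self.v_half_, self.z_g_)
            else:
                self.z_g_ = math.nan
                self.dg0_ = math.nan
        else:
            self.dg0_ = float(popt[0])
            self.z_g_ = float(popt[1])
            if ok:
                self.v_half_ = C.vhalf_from_dg0(self.dg0_, self.z_g_)
                self.k_ = C.slope_from_zg(self.z_g_, self.temperature)
            else:
                self.v_half_ = math.nan
                self.k_ = math.nan
        self.amplitude_ = float(popt[2]) if len(popt) == 3 else 1.0

        if ok:
            resid = f(v, *popt) - g
            self.rss_ = float(resid @ resid)
            # a midpoint outside the sampled range is not identifiable
            ok = bool(v.min() <= self.v_half_ <= v.max())
        else:
            self.rss_ = math.nan
        self.converged_ = ok
        return self

    def predict(self, v):
        v = np.asarray(v, dtype=float).ravel()
        return self.amplitude_ / (1.0 + np.exp((self.v_half_ - v) / self.k_))


def fit_boltzmann(
    curve: tuple[np.ndarray, np.ndarray] | list[tuple[float, float]],
    i_max: float = math.nan,
    **estimator_kw,
) -> ActivationFit:
    """Fit a Boltzmann to an activation curve; report both parameterizations."""
    if isinstance(curve, tuple) and len(curve) >= 2:
        v, g = np.asarray(curve[0], float), np.asarray(curve[1], float)
    else:
        arr = np.asarray(curve, dtype=float)
        v, g = arr[:, 0], arr[:, 1]
    est = BoltzmannActivation(**estimator_kw).fit(v, g)
    return ActivationFit(
        v_half_hat=est.v_half_,
        k_hat=est.k_,
        dg0_hat=est.dg0_,
        z_g_hat=est.z_g_,
        i_max=i_max,
        points=list(zip(v.tolist(), g.tolist())),
        rss=est.rss_,
        converged=est.converged_,
    )


def fit_activation(
    sweepset: SweepSet,
    blank_ms: float = DEFAULT_BLANK_MS,
    **estimator_kw,
) -> ActivationFit:
    """Build the normalized activation curve of one oocyte and fit it."""
    v, g, i_max = build_activation_curve(sweepset, blank_ms)
    return fit_boltzmann((v, g), i_max=i_max, **estimator_kw)
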