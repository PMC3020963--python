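"""Double-exponential fitting of deactivating tail currents.

Upon repolarization, open channels close along (at least) two kinetic
pathways, so the tail current decays as

    I(t) = A_f * exp(-(t - t0)/tau_fast) + A_s * exp(-(t - t0)/tau_slow) + C

The decay window starts at the tail-current extremum after a blank period
that excludes the capacitive transient, and runs to the end of the epoch.
Fitting is nonlinear least squares in an amplitude-linear / log-tau
parameterization with multi-start initialization; components are relabeled
so that ``tau_fast < tau_slow``.  When the two time constants are not
separable (ratio below a configurable threshold, or one component carries
a negligible amplitude) a single-exponential fallback is reported with
``tau_slow = NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator

from .models import SweepSet

__all__ = [
    "FitWindow",
    "TailFit",
    "DoubleExponentialDecay",
    "find_decay_window",
    "fit_double_exponential",
    "fit_tails",
]

#: Blank period (ms) skipped at the start of a tail epoch before looking
#: for the current extremum.  Eight capacitive time constants: the
#: residual step transient is then < 0.05% of its amplitude, which keeps
#: it from biasing the fastest tails (a 5 ms blank leaves ~0.7% of a
#: transient that is several-fold larger than the tail itself).
DEFAULT_BLANK_MS = 8.0


@dataclass(frozen=True)
class FitWindow:
    t_start: float  # ms, epoch-relative
    t_end: float  # ms
    flagged: bool = False  # no usable extremum was found


@dataclass
class TailFit:
    """Bi-exponential fit of one tail trace."""

    voltage: float | None
    tau_fast: float  # ms
    tau_slow: float  # ms (NaN for the single-exponential fallback)
    a_fast: float  # uA
    a_slow: float  # uA
    offset: float  # uA
    rel_amp_fast: float  # |A_f| / (|A_f| + |A_s|)
    fit_window: FitWindow
    rss: float  # uA^2
    converged: bool
    n_components: int = 2


def find_decay_window(
    time: np.ndarray,
    trace: np.ndarray,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> FitWindow:
    """Locate the decaying portion of a tail trace.

    The window starts at the extremum (largest absolute current) found
    after the blank period and ends at the end of the epoch.  A flat or
    empty trace is flagged and the window falls back to everything after
    the blank period.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    i0 = int(np.searchsorted(time, time[0] + blank_ms))
    i0 = min(i0, time.size - 1)
    seg = trace[i0:]
    if seg.size < 2 or np.allclose(seg, 0.0):
        return FitWindow(float(time[i0]), float(time[-1]), flagged=True)
    j = i0 + int(np.argmax(np.abs(seg)))
    # an extremum deep into the epoch leaves nothing to fit; it is a noise
    # artifact on a small signal, not a decay onset
    if time[-1] - time[j] < 0.25 * (time[-1] - time[i0]):
        return FitWindow(float(time[i0]), float(time[-1]), flagged=True)
    return FitWindow(float(time[j]), float(time[-1]), flagged=False)


def _biexp_residual(x, t, y):
    a1, a2, c, l1, l2 = x
    return a1 * np.exp(-t / math.exp(l1)) + a2 * np.exp(-t / math.exp(l2)) + c - y


def _biexp_jac(x, t, y):
    a1, a2, c, l1, l2 = x
    t1, t2 = math.exp(l1), math.exp(l2)
    e1, e2 = np.exp(-t / t1), np.exp(-t / t2)
    return np.column_stack(
        [e1, e2, np.ones_like(t), a1 * e1 * t / t1, a2 * e2 * t / t2]
    )


def _monoexp_residual(x, t, y):
    a, c, l = x
    return a * np.exp(-t / math.exp(l)) + c - y


def _monoexp_jac(x, t, y):
    a, c, l = x
    tau = math.exp(l)
    e = np.exp(-t / tau)
    return np.column_stack([e, np.ones_like(t), a * e * t / tau])


def _linear_amplitudes(t, y, taus):
    basis = np.column_stack([np.exp(-t / tau) for tau in taus] + [np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return coef


class DoubleExponentialDecay(BaseEstimator):
    """Least-squares bi-exponential decay model, scikit-learn style.

    Parameters
    ----------
    tau_ratio_min : float
        Minimum ``tau_slow / tau_fast`` required to report two components;
        below it a single-exponential fallback is used.
    min_component_frac : float
        Minimum relative amplitude of either component; below it the
        second component is considered unidentifiable.
    f_alpha : float
        Significance level of the extra-sum-of-squares F-test comparing
        the two-component fit against the nested single-exponential fit.
        If the second component does not improve the fit significantly it
        is dropped; this stops a noise blip from being reported as a fast
        component (and stealing the tau_fast label) when the true tail is
        effectively single-exponential.
    tau_bound_factors : (float, float)
        Lower/upper tau bounds as multiples of the sample interval and
        the window length, respectively.

    Fitted attributes (set by :meth:`fit`): ``tau_fast_``, ``tau_slow_``,
    ``amp_fast_``, ``amp_slow_``, ``offset_``, ``rss_``, ``converged_``,
    ``n_components_``.
    """

    def __init__(
        self,
        tau_ratio_min: float = 1.5,
        min_component_frac: float = 1e-3,
        f_alpha: float = 1e-3,
        tau_bound_factors: tuple[float, float] = (0.5, 10.0),
        max_nfev: int = 2000,
    ):
        self.tau_ratio_min = tau_ratio_min
        self.min_component_frac = min_component_frac
        self.f_alpha = f_alpha
        self.tau_bound_factors = tau_bound_factors
        self.max_nfev = max_nfev

    # -- internals ----------------------------------------------------
    def _solve(self, residual, jac, x0, bounds, t, y):
        return least_squares(
            residual,
            x0,
            jac=jac,
            bounds=bounds,
            args=(t, y),
            method="trf",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            max_nfev=self.max_nfev,
        )

    def _fit_double(self, t, y, lo, hi):
        w = t[-1] if t[-1] > 0 else 1.0
        starts = [(w / 10, w / 2), (w / 30, w / 3), (w / 100, w / 5)]
        best = None
        bounds = (
            [-np.inf, -np.inf, -np.inf, math.log(lo), math.log(lo)],
            [np.inf, np.inf, np.inf, math.log(hi), math.log(hi)],
        )
        for t1, t2 in starts:
            t1 = float(np.clip(t1, lo * 1.01, hi * 0.99))
            t2 = float(np.clip(t2, lo * 1.01, hi * 0.99))
            if t1 == t2:
                t2 = min(t1 * 2.0, hi * 0.99)
            a1, a2, c = _linear_amplitudes(t, y, (t1, t2))
            x0 = [a1, a2, c, math.log(t1), math.log(t2)]
            try:
                res = self._solve(_biexp_residual, _biexp_jac, x0, bounds, t, y)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        return best

    def _fit_single(self, t, y, lo, hi):
        w = t[-1] if t[-1] > 0 else 1.0
        bounds = ([-np.inf, -np.inf, math.log(lo)], [np.inf, np.inf, math.log(hi)])
        best = None
        for tau in (w / 10, w / 3, w / 30):
            tau = float(np.clip(tau, lo * 1.01, hi * 0.99))
            a, c = _linear_amplitudes(t, y, (tau,))
            try:
                res = self._solve(
                    _monoexp_residual, _monoexp_jac, [a, c, math.log(tau)],
                    bounds, t, y,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        return best

    # -- estimator API ------------------------------------------------
    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size or t.size < 6:
            raise ValueError("need matching t/y vectors with >= 6 samples")
        t0 = t[0]
        t = t - t0
        dt = float(np.min(np.diff(t)))
        w = float(t[-1]) if t[-1] > 0 else 1.0
        lo = max(self.tau_bound_factors[0] * dt, 1e-12)
        hi = self.tau_bound_factors[1] * w

        double = self._fit_double(t, y, lo, hi)
        single = self._fit_single(t, y, lo, hi)
        use_single = double is None
        if double is not None:
            a1, a2, c, l1, l2 = double.x
            tau1, tau2 = math.exp(l1), math.exp(l2)
            if tau1 > tau2:
                tau1, tau2, a1, a2 = tau2, tau1, a2, a1
            amp_sum = abs(a1) + abs(a2)
            frac = min(abs(a1), abs(a2)) / amp_sum if amp_sum > 0 else 0.0
            if (
                not double.success
                or tau2 / tau1 < self.tau_ratio_min
                or frac < self.min_component_frac
            ):
                use_single = True
            elif single is not None and single.success:
                # extra-sum-of-squares F-test: is the 2nd component real?
                rss2 = 2.0 * double.cost
                rss1 = 2.0 * single.cost
                dof = t.size - 5
                if rss2 > 0 and dof > 0 and rss1 >= rss2:
                    f_stat = ((rss1 - rss2) / 2.0) / (rss2 / dof)
                    if f_dist.sf(f_stat, 2, dof) > self.f_alpha:
                        use_single = True

        if use_single:
            if single is None or not single.success:
                self.tau_fast_ = math.nan
                self.tau_slow_ = math.nan
                self.amp_fast_ = math.nan
                self.amp_slow_ = math.nan
                self.offset_ = math.nan
                self.rss_ = math.nan
                self.converged_ = False
                self.n_components_ = 0
                return self
            a, c, l = single.x
            self.tau_fast_ = math.exp(l)
            self.tau_slow_ = math.nan
            self.amp_fast_ = float(a)
            self.amp_slow_ = 0.0
            self.offset_ = float(c)
            self.rss_ = 2.0 * float(single.cost)
            self.converged_ = bool(single.success)
            self.n_components_ = 1
            return self

        self.tau_fast_ = float(tau1)
        self.tau_slow_ = float(tau2)
        self.amp_fast_ = float(a1)
        self.amp_slow_ = float(a2)
        self.offset_ = float(c)
        self.rss_ = 2.0 * float(double.cost)
        self.converged_ = bool(double.success)
        self.n_components_ = 2
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float).ravel()
        t = t - t[0]
        out = np.full_like(t, self.offset_, dtype=float)
        out += self.amp_fast_ * np.exp(-t / self.tau_fast_)
        if self.n_components_ == 2:
            out += self.amp_slow_ * np.exp(-t / self.tau_slow_)
        return out

    @property
    def rel_amp_fast_(self) -> float:
        if self.n_components_ == 1:
            return 1.0
        denom = abs(self.amp_fast_) + abs(self.amp_slow_)
        return abs(self.amp_fast_) / denom if denom > 0 else math.nan


def fit_double_exponential(
    time: np.ndarray,
    trace: np.ndarray,
    window: FitWindow | None = None,
    voltage: float | None = None,
    min_window_samples: int = 20,
    **estimator_kw,
) -> TailFit:
    """Fit a bi-exponential to the decaying portion of one tail trace."""
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if window is None:
        window = find_decay_window(time, trace)
    mask = (time >= window.t_start) & (time <= window.t_end)
    if int(mask.sum()) < min_window_samples:
        raise ValueError(
            f"fit window contains {int(mask.sum())} samples; "
            f"need at least {min_window_samples}"
        )
    est = DoubleExponentialDecay(**estimator_kw).fit(time[mask], trace[mask])
    return TailFit(
        voltage=voltage,
        tau_fast=est.tau_fast_,
        tau_slow=est.tau_slow_,
        a_fast=est.amp_fast_,
        a_slow=est.amp_slow_,
        offset=est.offset_,
        rel_amp_fast=est.rel_amp_fast_,
        fit_window=window,
        rss=est.rss_,
        converged=est.converged_,
        n_components=est.n_components_,
    )


def fit_tails(
    sweepset: SweepSet,
    v_min: float = -160.0,
    v_max: float = -50.0,
    blank_ms: float = DEFAULT_BLANK_MS,
    **estimator_kw,
) -> list[TailFit]:
    """Fit every repolarization tail of a deactivation sweep set.

    Voltages outside ``v_min..v_max`` are skipped; results are ordered by
    ascending voltage.  The sweep set must be leak-subtracted first.
    """
    if not sweepset.is_leak_subtracted:
        raise ValueError("fit_tails requires a leak-subtracted sweep set")
    proto = sweepset.protocol
    sl = proto.epoch_slices()[proto.sweep_variable]
    t = sweepset.time[sl] - sweepset.time[sl.start]
    fits = []
    for s, level in enumerate(proto.sweep_levels):
        if not v_min <= level <= v_max:
            continue
        trace = sweepset.currents[s, sl]
        window = find_decay_window(t, trace, blank_ms)
        fits.append(
            fit_double_exponential(
                t, trace, window, voltage=float(level), **estimator_kw
            )
        )
    fits.sort(key=lambda f: f.voltage)
    return fits
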