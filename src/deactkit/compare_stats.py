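"""Construct-level aggregation and mutant-versus-wild-type statistics.

Per-oocyte deactivation time constants at the common driving force are
aggregated to mean +/- SEM per construct.  Differences from wild type are
tested with a one-way ANOVA across all constructs followed by Dunnett's
many-to-one comparison against the wild-type control; each mutant is then
classified as faster, slower or unchanged from the sign of the difference
and the Dunnett p-value at level alpha.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConstructSummary", "summarize", "summarize_all", "report"]


@dataclass
class ConstructSummary:
    construct_label: str
    n: int
    tau_mean: float  # ms at the target driving force
    tau_sem: float
    ratio_to_wt: float
    p_vs_wt: float  # NaN for the control itself or untestable groups
    classification: str  # faster | slower | unchanged
    v_half_mean: float = math.nan
    v_half_sem: float = math.nan
    dg0_mean: float = math.nan
    dg0_sem: float = math.nan
    warning: str = ""


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else math.nan
    return m, sem


def summarize_all(
    tau_by_construct: dict[str, np.ndarray],
    wt_label: str = "WT",
    alpha: float = 0.05,
    extras: dict[str, dict[str, np.ndarray]] | None = None,
) -> tuple[list[ConstructSummary], float]:
    """Summaries for every construct plus the overall ANOVA p-value.

    ``extras`` may carry per-construct arrays under keys ``v_half`` and
    ``dg0``; their mean +/- SEM is folded into the summaries.  Groups with
    fewer than two oocytes are reported but not tested (classification
    ``unchanged`` with a warning).
    """
    if wt_label not in tau_by_construct:
        raise KeyError(f"wild-type group {wt_label!r} missing")
    groups = {k: np.asarray(v, dtype=float) for k, v in tau_by_construct.items()}
    wt = groups[wt_label]
    wt_mean = float(np.mean(wt))

    testable = [k for k, v in groups.items() if v.size >= 2]
    anova_p = math.nan
    if len(testable) >= 2:
        anova_p = float(stats.f_oneway(*[groups[k] for k in testable]).pvalue)

    mutants = [k for k in groups if k != wt_label]
    dunnett_p: dict[str, float] = {}
    dunnett_ok = [k for k in mutants if groups[k].size >= 2 and wt.size >= 2]
    if dunnett_ok:
        # fixed rng: the Dunnett p-value integrates a multivariate t
        # numerically; seeding makes summaries byte-reproducible
        res = stats.dunnett(
            *[groups[k] for k in dunnett_ok], control=wt,
            rng=np.random.default_rng(0),
        )
        for k, p in zip(dunnett_ok, res.pvalue):
            dunnett_p[k] = float(p)

    extras = extras or {}
    out = []
    for label in [wt_label] + mutants:
        x = groups[label]
        m, sem = _mean_sem(x)
        warning = ""
        if label == wt_label:
            p, cls = math.nan, "unchanged"
            if x.size < 2:
                warning = "wild-type group has n < 2; no comparisons possible"
        elif label in dunnett_p:
            p = dunnett_p[label]
            if p < alpha:
                cls = "faster" if m < wt_mean else "slower"
            else:
                cls = "unchanged"
        else:
            p, cls = math.nan, "unchanged"
            warning = "n < 2 in this or the control group; no variance estimate"
        ex = extras.get(label, {})
        vh = _mean_sem(ex["v_half"]) if "v_half" in ex else (math.nan, math.nan)
        dg = _mean_sem(ex["dg0"]) if "dg0" in ex else (math.nan, math.nan)
        out.append(
            ConstructSummary(
                construct_label=label,
                n=int(x.size),
                tau_mean=m,
                tau_sem=sem,
                ratio_to_wt=m / wt_mean if wt_mean != 0 else math.nan,
                p_vs_wt=p,
                classification=cls,
                v_half_mean=vh[0],
                v_half_sem=vh[1],
                dg0_mean=dg[0],
                dg0_sem=dg[1],
                warning=warning,
            )
        )
    return out, anova_p


def summarize(
    mutant_taus,
    wt_taus,
    alpha: float = 0.05,
    label: str = "mutant",
    wt_label: str = "WT",
) -> ConstructSummary:
    """Two-group convenience wrapper: one mutant against wild type."""
    summaries, _ = summarize_all(
        {wt_label: np.asarray(wt_taus), label: np.asarray(mutant_taus)},
        wt_label=wt_label,
        alpha=alpha,
    )
    return next(s for s in summaries if s.construct_label == label)


_POINT_RE = re.compile(r"^[A-Z](\d+)[A-Z]$")


def _order_key(label: str, wt_label: str):
    """WT first, point mutants by residue position, then deletions/linkers."""
    if label == wt_label:
        return (0, 0, label)
    m = _POINT_RE.fullmatch(label)
    if m:
        return (1, int(m.group(1)), label)
    return (2, 0, label)


def report(
    summaries: list[ConstructSummary],
    wt_label: str = "WT",
    anova_p: float = math.nan,
) -> tuple[pd.DataFrame, dict]:
    """Deterministically ordered table plus a machine-readable dict."""
    ordered = sorted(summaries, key=lambda s: _order_key(s.construct_label, wt_label))
    table = pd.DataFrame(
        {
            "construct": [s.construct_label for s in ordered],
            "n": [s.n for s in ordered],
            "tau_fast_at_target_ms": [s.tau_mean for s in ordered],
            "tau_sem_ms": [s.tau_sem for s in ordered],
            "ratio_to_wt": [s.ratio_to_wt for s in ordered],
            "p_vs_wt": [s.p_vs_wt for s in ordered],
            "classification": [s.classification for s in ordered],
        }
    )
    payload = {
        "anova_p": anova_p,
        "constructs": [
            {
                "label": s.construct_label,
                "n": s.n,
                "tau_fast_at_target_ms": s.tau_mean,
                "tau_sem_ms": s.tau_sem,
                "ratio_to_wt": s.ratio_to_wt,
                "p_vs_wt": None if math.isnan(s.p_vs_wt) else s.p_vs_wt,
                "classification": s.classification,
                "v_half_mean_mv": None if math.isnan(s.v_half_mean) else s.v_half_mean,
                "dg0_mean_kj_mol": None if math.isnan(s.dg0_mean) else s.dg0_mean,
                "warning": s.warning,
            }
            for s in ordered
        ],
    }
    return table, payload
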