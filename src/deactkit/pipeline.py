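"""End-to-end orchestration: simulate, preprocess, fit, convert, compare.

The full reproduction run simulates an n-replicate cohort for every
configured construct (activation and deactivation protocols per oocyte),
leak-subtracts every sweep, fits the per-oocyte activation Boltzmann and
the per-voltage tail bi-exponentials, converts the repolarization voltages
to electrochemical driving forces using the construct's pooled activation
energetics, interpolates the fast time constant at the target driving
force per oocyte, and compares every mutant to wild type.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import cohorts
from .activation import ActivationFit, fit_activation
from .compare_stats import report, summarize_all
from .driving_force import DEFAULT_TARGET_DF, build_curve, tau_at_driving_force
from .models import GatingModel
from .preprocess import subtract_leak
from .synthetic import OocyteRecording, make_cohort
from .tail_kinetics import TailFit, fit_tails

__all__ = ["ConstructSpec", "RunConfig", "ConstructResult", "analyze_construct",
           "run_all", "paper_run_config"]


class ConstructSpec(BaseModel):
    """Generator parameters for one construct in a run configuration."""

    label: str
    n_oocytes: int = Field(default=10, ge=1)
    v_half: float
    dg0: float | None = None
    slope_k: float | None = None
    tau_fast_ref: float
    tau_slow_ref: float | None = None
    tau_voltage_efold: float
    amp_fast_frac_ref: float = 0.85
    g_max: float = 30.0
    g_leak: float = 0.3
    oocyte_cv: float = 0.10

    @model_validator(mode="after")
    def _one_parameterization(self):
        if (self.dg0 is None) == (self.slope_k is None):
            raise ValueError(
                f"construct {self.label!r}: give exactly one of dg0 or slope_k"
            )
        return self

    def gating_model(self) -> GatingModel:
        kw = dict(
            tau_fast_ref=self.tau_fast_ref,
            tau_slow_ref=self.tau_slow_ref or 5.0 * self.tau_fast_ref,
            tau_voltage_efold=self.tau_voltage_efold,
            amp_fast_frac_ref=self.amp_fast_frac_ref,
            g_max=self.g_max,
            g_leak=self.g_leak,
            oocyte_cv=self.oocyte_cv,
        )
        if self.dg0 is not None:
            return GatingModel.from_midpoint_energy(
                self.label, v_half=self.v_half, dg0=self.dg0, **kw
            )
        return GatingModel.from_voltage(
            self.label, v_half=self.v_half, slope_k=self.slope_k, **kw
        )


class RunConfig(BaseModel):
    """Validated configuration of a full reproduction run."""

    constructs: list[ConstructSpec]
    seed: int = 0
    wt_label: str = "WT"
    target_df: float = DEFAULT_TARGET_DF
    alpha: float = 0.05
    log_tau_interpolation: bool = True
    deact_noise_sd_frac: float = 0.01
    act_noise_sd_frac: float = 0.02

    @model_validator(mode="after")
    def _labels(self):
        labels = [c.label for c in self.constructs]
        if len(set(labels)) != len(labels):
            raise ValueError("construct labels must be unique")
        if self.wt_label not in labels:
            raise ValueError(f"wild-type construct {self.wt_label!r} missing")
        return self


def paper_run_config(labels: list[str] | None = None, seed: int = 0) -> RunConfig:
    """Run configuration for the encoded reference constructs."""
    labels = labels or cohorts.construct_labels()
    specs = []
    for lbl in labels:
        m = cohorts.paper_model(lbl)
        specs.append(
            ConstructSpec(
                label=m.construct_label,
                n_oocytes=cohorts.n_oocytes(m.construct_label),
                v_half=m.v_half,
                dg0=m.dg0,
                tau_fast_ref=m.tau_fast_ref,
                tau_slow_ref=m.tau_slow_ref,
                tau_voltage_efold=m.tau_voltage_efold,
                amp_fast_frac_ref=m.amp_fast_frac_ref,
                g_max=m.g_max,
                g_leak=m.g_leak,
                oocyte_cv=m.oocyte_cv,
            )
        )
    return RunConfig(constructs=specs, seed=seed)


@dataclass
class ConstructResult:
    """Per-construct analysis products of a reproduction run."""

    label: str
    activation_fits: list[ActivationFit]
    tail_fits: list[list[TailFit]]  # per oocyte
    pooled_dg0: float
    pooled_z_g: float
    tau_at_target: np.ndarray  # per oocyte, ms
    v_half: np.ndarray  # per oocyte, mV
    dg0: np.ndarray  # per oocyte, kJ/mol


def analyze_construct(
    recordings: list[OocyteRecording],
    target_df: float = DEFAULT_TARGET_DF,
    log_tau: bool = True,
    per_oocyte_conversion: bool = True,
) -> ConstructResult:
    """Run the full analysis chain on one construct's recordings.

    By default each oocyte's voltages are converted to driving forces with
    that oocyte's own fitted activation energetics; the per-oocyte fit
    errors then average out across the cohort.  With
    ``per_oocyte_conversion=False`` the construct's pooled (mean) dG0 and
    z_g are used for every oocyte instead — this matches plotting all
    oocytes on one shared driving-force axis, but any error in the pooled
    fit is common to the whole cohort and does not average down.
    """
    act_fits: list[ActivationFit] = []
    tail_fits: list[list[TailFit]] = []
    for rec in recordings:
        act_fits.append(fit_activation(subtract_leak(rec.activation)))
        tail_fits.append(fit_tails(subtract_leak(rec.deactivation)))

    good = [f for f in act_fits if f.converged]
    if not good:
        raise RuntimeError("no converged activation fit; cannot pool energetics")
    pooled_dg0 = float(np.mean([f.dg0_hat for f in good]))
    pooled_z_g = float(np.mean([f.z_g_hat for f in good]))

    label = recordings[0].construct_label
    taus = []
    for afit, fits in zip(act_fits, tail_fits):
        if per_oocyte_conversion and afit.converged:
            dg0, z_g = afit.dg0_hat, afit.z_g_hat
        else:
            dg0, z_g = pooled_dg0, pooled_z_g
        curve = build_curve(fits, dg0, z_g, label)
        taus.append(tau_at_driving_force(curve, target_df, log_tau=log_tau))
    return ConstructResult(
        label=label,
        activation_fits=act_fits,
        tail_fits=tail_fits,
        pooled_dg0=pooled_dg0,
        pooled_z_g=pooled_z_g,
        tau_at_target=np.array(taus),
        v_half=np.array([f.v_half_hat for f in act_fits]),
        dg0=np.array([f.dg0_hat for f in act_fits]),
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_all(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Execute a full reproduction run and write the result bundle.

    Writes ``activation.csv``, ``tails.csv``, ``driving_force.csv``,
    ``summary.json`` and ``run.log`` under ``outdir``; returns the summary
    dict.  Deterministic under (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)

    models = [c.gating_model() for c in config.constructs]
    n_map = {c.label: c.n_oocytes for c in config.constructs}
    cohort = make_cohort(
        models,
        n_map,
        seed,
        act_noise_sd_frac=config.act_noise_sd_frac,
        deact_noise_sd_frac=config.deact_noise_sd_frac,
    )

    log_lines = [
        f"deactkit reproduction run, seed={seed}",
        f"config_hash={_config_hash(config)}",
        f"constructs={[c.label for c in config.constructs]}",
    ]

    results: dict[str, ConstructResult] = {}
    act_rows, tail_rows, df_rows = [], [], []
    for label, recs in cohort.items():
        res = analyze_construct(
            recs, target_df=config.target_df, log_tau=config.log_tau_interpolation
        )
        results[label] = res
        log_lines.append(
            f"{label}: n={len(recs)} pooled dG0={res.pooled_dg0:.3f} kJ/mol "
            f"z_g={res.pooled_z_g:.3f}"
        )
        for rec, afit, tfits, tau in zip(
            recs, res.activation_fits, res.tail_fits, res.tau_at_target
        ):
            act_rows.append(
                dict(
                    construct=label,
                    oocyte_id=rec.oocyte_id,
                    v_half_mv=afit.v_half_hat,
                    slope_k_mv=afit.k_hat,
                    dg0_kj_mol=afit.dg0_hat,
                    z_g=afit.z_g_hat,
                    converged=afit.converged,
                )
            )
            df_rows.append(
                dict(construct=label, oocyte_id=rec.oocyte_id, tau_at_target_ms=tau)
            )
            for f in tfits:
                tail_rows.append(
                    dict(
                        construct=label,
                        oocyte_id=rec.oocyte_id,
                        voltage_mv=f.voltage,
                        tau_fast_ms=f.tau_fast,
                        tau_slow_ms=f.tau_slow,
                        rel_amp_fast=f.rel_amp_fast,
                        converged=f.converged,
                    )
                )

    pd.DataFrame(act_rows).to_csv(outdir / "activation.csv", index=False)
    pd.DataFrame(tail_rows).to_csv(outdir / "tails.csv", index=False)
    pd.DataFrame(df_rows).to_csv(outdir / "driving_force.csv", index=False)

    summaries, anova_p = summarize_all(
        {lbl: res.tau_at_target for lbl, res in results.items()},
        wt_label=config.wt_label,
        alpha=config.alpha,
        extras={
            lbl: {"v_half": res.v_half, "dg0": res.dg0}
            for lbl, res in results.items()
        },
    )
    table, payload = report(summaries, config.wt_label, anova_p)
    payload["anova_p"] = None if math.isnan(anova_p) else anova_p
    payload["seed"] = seed
    payload["target_df_kj_mol"] = config.target_df
    payload["config_hash"] = _config_hash(config)

    (outdir / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    log_lines.append(f"anova_p={anova_p}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return payload
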