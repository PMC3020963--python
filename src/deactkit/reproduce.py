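"""Parameter-recovery experiments on synthetic cohorts.

The reported electrophysiology values are measurements on real oocytes;
here they are reproduced as recovery experiments: a synthetic cohort is
generated with the reported values as ground truth and the full analysis
chain (leak subtraction, window detection, tail fitting, Boltzmann
fitting, driving-force conversion) must recover them.  These helpers run
one such experiment per call and are deterministic under the seed.

Different constructs are given disjoint oocyte-id ranges so their
between-oocyte jitter draws are independent.
"""

from __future__ import annotations

import numpy as np

from . import cohorts
from .activation import ActivationFit, fit_activation
from .pipeline import ConstructResult, analyze_construct
from .preprocess import subtract_leak
from .synthetic import (
    OocyteRecording,
    activation_protocol,
    deactivation_protocol,
    simulate_sweepset,
)
from .tail_kinetics import fit_double_exponential, find_decay_window

__all__ = [
    "deactivation_tau_cohort",
    "activation_fit_cohort",
    "driving_force_cohort",
]


def deactivation_tau_cohort(
    label: str,
    n: int,
    seed: int,
    voltage: float = -120.0,
    id_offset: int = 0,
    noise_sd_frac: float = 0.01,
) -> np.ndarray:
    """Per-oocyte fitted fast time constants (ms) at one tail voltage.

    Simulates ``n`` oocytes of the given construct with the deactivation
    protocol, leak-subtracts each recording and fits the bi-exponential to
    the tail at ``voltage``.
    """
    model = cohorts.paper_model(label)
    proto = deactivation_protocol()
    sl = proto.epoch_slices()[proto.sweep_variable]
    out = []
    for i in range(n):
        ss = simulate_sweepset(
            model, proto, id_offset + i, seed, noise_sd_frac=noise_sd_frac
        )
        sub = subtract_leak(ss)
        t = sub.time[sl] - sub.time[sl.start]
        trace = sub.currents[sub.sweep_index(voltage), sl]
        fit = fit_double_exponential(
            t, trace, find_decay_window(t, trace), voltage=voltage
        )
        out.append(fit.tau_fast)
    return np.asarray(out)


def activation_fit_cohort(
    label: str,
    n: int,
    seed: int,
    id_offset: int = 0,
    noise_sd_frac: float = 0.02,
) -> list[ActivationFit]:
    """Per-oocyte Boltzmann activation fits for a synthetic cohort."""
    model = cohorts.paper_model(label)
    proto = activation_protocol()
    fits = []
    for i in range(n):
        ss = simulate_sweepset(
            model, proto, id_offset + i, seed, noise_sd_frac=noise_sd_frac
        )
        fits.append(fit_activation(subtract_leak(ss)))
    return fits


def driving_force_cohort(
    label: str,
    n: int,
    seed: int,
    id_offset: int = 0,
    target_df: float = -30.0,
    act_noise_sd_frac: float = 0.02,
    deact_noise_sd_frac: float = 0.01,
) -> ConstructResult:
    """Full chain through the driving-force comparison for one construct.

    Each oocyte records both protocols with shared jittered parameters;
    voltages are converted with the construct's pooled activation
    energetics and tau_fast is interpolated at ``target_df``.
    """
    model = cohorts.paper_model(label)
    act_proto = activation_protocol()
    deact_proto = deactivation_protocol()
    recs = []
    for i in range(n):
        oid = id_offset + i
        recs.append(
            OocyteRecording(
                construct_label=label,
                oocyte_id=oid,
                activation=simulate_sweepset(
                    model, act_proto, oid, seed, noise_sd_frac=act_noise_sd_frac
                ),
                deactivation=simulate_sweepset(
                    model, deact_proto, oid, seed, noise_sd_frac=deact_noise_sd_frac
                ),
            )
        )
    return analyze_construct(recs, target_df=target_df)
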