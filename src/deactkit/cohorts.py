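"""Reference construct library: WT hERG and the N-terminal tail mutants.

Generator parameters for each construct are anchored to the reported
two-electrode voltage-clamp measurements:

* activation energetics: WT V0.5 = -23.2 mV with dG0 = -6.8 kJ/mol;
  the 2-9 deletion V0.5 = -5.6 mV with dG0 = -1.9 kJ/mol; the GGS-linker
  replacement V0.5 = -18.5 mV at the WT slope; the 2-25 deletion and all
  point mutants carry WT activation values (their shifts are below 10 mV
  and are not modeled).
* fast deactivation time constants: anchored either at -120 mV (WT
  33.7 ms, d2-9 11.4 ms, d2-25 8.7 ms, GGS 7.5 ms) or at the -30 kJ/mol
  driving force (R5A 16.5, G6A 12.7, P10A 44.4, T13A 38.2, D16A 54.2,
  I19A 19.2, R20A 20.4 ms).  The shared e-fold voltage dependence of the
  tau(V) law is calibrated from the two WT anchors (33.7 ms at -120 mV
  and 28.5 ms at -30 kJ/mol), giving one e-fold per ~33 mV.

Constructs without a reported time constant default to WT kinetics (they
were classified as unchanged).  The slow component is set at five times
the fast component, matching the WT ratio.
"""

from __future__ import annotations

import math

from . import constants as C
from .driving_force import voltage_at_driving_force
from .models import GatingModel

__all__ = [
    "WT_LABEL",
    "DEFAULT_EFOLD_MV",
    "paper_model",
    "paper_cohort",
    "construct_labels",
    "n_oocytes",
]

WT_LABEL = "WT"

# -- activation anchors (mV, kJ/mol) ----------------------------------
WT_V_HALF = -23.2
WT_DG0 = -6.8
D29_V_HALF = -5.6
D29_DG0 = -1.9
GGS_V_HALF = -18.5

WT_Z_G = WT_DG0 / (C.FARADAY * WT_V_HALF / 1000.0)

# -- deactivation anchors (ms) ----------------------------------------
WT_TAU_FAST_120 = 33.7
WT_TAU_FAST_DF30 = 28.5
TAU_REF_VOLTAGE = -120.0
TARGET_DF = -30.0

#: Voltage (mV) at which the WT driving force equals -30 kJ/mol.
_WT_E30 = voltage_at_driving_force(TARGET_DF, WT_DG0, WT_Z_G)

#: e-fold voltage dependence of both tail time constants (mV), calibrated
#: so the WT tau(V) law passes through both WT anchors.
DEFAULT_EFOLD_MV = (_WT_E30 - TAU_REF_VOLTAGE) / math.log(
    WT_TAU_FAST_DF30 / WT_TAU_FAST_120
)

#: tau_slow / tau_fast at the anchor voltage (WT-like for all constructs).
SLOW_FAST_RATIO = 5.0

# Per-construct anchors: either tau at -120 mV or tau at -30 kJ/mol, the
# activation parameterization, and the number of oocytes studied.
_CONSTRUCTS: dict[str, dict] = {
    "WT": dict(tau120=33.7, n=11),
    "Δ2-9": dict(tau120=11.4, n=14, v_half=D29_V_HALF, dg0=D29_DG0),
    "Δ2-25": dict(tau120=8.7, n=5),
    "GGS": dict(tau120=7.5, n=10, v_half=GGS_V_HALF),
    "R5A": dict(tau30=16.5, n=8),
    "G6A": dict(tau30=12.7, n=7),
    "P10A": dict(tau30=44.4, n=14),
    "T13A": dict(tau30=38.2, n=15),
    "D16A": dict(tau30=54.2, n=10),
    "I19A": dict(tau30=19.2, n=13),
    "R20A": dict(tau30=20.4, n=20),
}

#: Remaining alanine-scan constructs, classified as unchanged from WT;
#: no quantitative anchors were reported, so they carry WT kinetics.
_UNCHANGED = (
    "P2A", "V3A", "R4A", "H7A", "V8A", "A9V", "Q11A", "N12A",
    "F14A", "L15A", "T17A", "I18A", "K21A", "F22A", "E23A",
)
for _label in _UNCHANGED:
    _CONSTRUCTS[_label] = dict(tau120=WT_TAU_FAST_120, n=10)


def construct_labels() -> list[str]:
    """All encoded constructs, wild type first."""
    return list(_CONSTRUCTS)


def n_oocytes(label: str) -> int:
    """Reported number of oocytes for a construct (10 where unreported)."""
    return _CONSTRUCTS[label]["n"]


#: ASCII aliases for the deletion constructs.
_ALIASES = {"d2-9": "Δ2-9", "d2-25": "Δ2-25"}


def paper_model(label: str, **overrides) -> GatingModel:
    """Gating model for one construct, anchored to the reported values.

    Keyword overrides are forwarded to :class:`GatingModel` (e.g.
    ``noise_sd_frac=0``, ``oocyte_cv=0`` for noiseless variants).
    """
    label = _ALIASES.get(label, label)
    if label not in _CONSTRUCTS:
        raise KeyError(
            f"unknown construct {label!r}; known: {sorted(_CONSTRUCTS)}"
        )
    spec = _CONSTRUCTS[label]
    v_half = spec.get("v_half", WT_V_HALF)
    if "dg0" in spec:
        dg0 = spec["dg0"]
        z_g = dg0 / (C.FARADAY * v_half / 1000.0)
    else:
        z_g = WT_Z_G  # unchanged slope
        dg0 = C.dg0_from_vhalf(v_half, z_g)

    if "tau120" in spec:
        tau_fast_ref = spec["tau120"]
    else:
        # anchor at the -30 kJ/mol driving force of this construct
        e30 = voltage_at_driving_force(TARGET_DF, dg0, z_g)
        tau_fast_ref = spec["tau30"] * math.exp(
            -(e30 - TAU_REF_VOLTAGE) / DEFAULT_EFOLD_MV
        )

    kw = dict(
        tau_fast_ref=tau_fast_ref,
        tau_slow_ref=SLOW_FAST_RATIO * tau_fast_ref,
        tau_voltage_efold=DEFAULT_EFOLD_MV,
        tau_ref_voltage=TAU_REF_VOLTAGE,
    )
    kw.update(overrides)
    return GatingModel.from_midpoint_energy(label, v_half=v_half, dg0=dg0, **kw)


def paper_cohort(labels: list[str] | None = None, **overrides) -> list[GatingModel]:
    """Gating models for a set of constructs (default: all encoded)."""
    return [paper_model(lbl, **overrides) for lbl in (labels or construct_labels())]
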