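"""Physical constants and thermodynamic conversions for channel gating.

The steady-state open probability of a voltage-gated channel is described
by a two-state Boltzmann distribution.  Two equivalent parameterizations
are used throughout the package:

* voltage form:  ``g/g_max = 1 / (1 + exp((V0.5 - V) / k))`` with midpoint
  ``V0.5`` (mV) and slope factor ``k`` (mV);
* energetic form: ``g/g_max = 1 / (1 + exp((dG0 - z_g*E*F) / RT))`` with the
  chemical work of activation at 0 mV ``dG0`` (kJ/mol) and the effective
  gating charge ``z_g`` (elementary charges crossing the full field).

The two are related by ``V0.5 = dG0 / (z_g * F)`` and ``k = R*T / (z_g * F)``
(voltages in volts).  All conversion helpers below take millivolts and return
kJ/mol unless noted otherwise.
"""

from __future__ import annotations

import numpy as np

#: Faraday constant in kJ mol^-1 V^-1 per elementary charge.
FARADAY = 96.485

#: Universal gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT = 8.31446e-3

#: Default recording temperature (K); room temperature, 22 degC.
T_ROOM = 295.15


def thermal_energy(temperature: float = T_ROOM) -> float:
    """R*T in kJ/mol (about 2.454 kJ/mol at room temperature)."""
    return GAS_CONSTANT * temperature


def zg_from_slope(slope_k_mv: float, temperature: float = T_ROOM) -> float:
    """Effective gating charge from the Boltzmann slope factor (mV)."""
    if slope_k_mv <= 0:
        raise ValueError("slope factor must be positive")
    return thermal_energy(temperature) / (FARADAY * slope_k_mv / 1000.0)


def slope_from_zg(z_g: float, temperature: float = T_ROOM) -> float:
    """Boltzmann slope factor (mV) from the effective gating charge."""
    if z_g <= 0:
        raise ValueError("gating charge must be positive")
    return 1000.0 * thermal_energy(temperature) / (FARADAY * z_g)


def dg0_from_vhalf(v_half_mv: float, z_g: float) -> float:
    """Chemical work of activation at 0 mV (kJ/mol) from the midpoint."""
    return z_g * FARADAY * v_half_mv / 1000.0


def vhalf_from_dg0(dg0: float, z_g: float) -> float:
    """Half-activation voltage (mV) from the energetic parameters."""
    return 1000.0 * dg0 / (z_g * FARADAY)


def boltzmann_open_fraction(v_mv, v_half_mv: float, slope_k_mv: float):
    """Steady-state open fraction ``1/(1+exp((V0.5-V)/k))``; vectorized."""
    v = np.asarray(v_mv, dtype=float)
    return 1.0 / (1.0 + np.exp((v_half_mv - v) / slope_k_mv))
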