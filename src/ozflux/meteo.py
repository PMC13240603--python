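"""Moist-air thermodynamics used by both the generator and the analysis.

All functions are vectorised over numpy arrays / pandas Series. Units follow
tower conventions: temperature degC, pressure kPa, vapor pressure kPa,
relative humidity percent.
"""

from __future__ import annotations

import numpy as np

from .constants import CONST


def saturation_vapor_pressure(t_c):
    """Saturation vapor pressure (kPa) from the Magnus form.

    es(T) = 0.6108 * exp(17.27 T / (T + 237.3)), T in degC.
    """
    t_c = np.asarray(t_c, dtype=float)
    if np.any(t_c <= -60.0):
        raise ValueError("temperature below -60 degC outside Magnus validity")
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def vapor_pressure(t_c, rh_pct):
    """Actual vapor pressure (kPa) from temperature and RH (%)."""
    return saturation_vapor_pressure(t_c) * np.asarray(rh_pct, dtype=float) / 100.0


def vpd(t_c, rh_pct):
    """Air vapor pressure deficit, kPa."""
    es = saturation_vapor_pressure(t_c)
    return es * (1.0 - np.asarray(rh_pct, dtype=float) / 100.0)


def latent_heat_vaporization(t_c):
    """Latent heat of vaporization of water, J kg^-1 (linear in T)."""
    return (2.501 - 0.00237 * np.asarray(t_c, dtype=float)) * 1e6


def specific_humidity(t_c, rh_pct, p_kpa):
    """Specific humidity (kg kg^-1) of moist air."""
    e = vapor_pressure(t_c, rh_pct)
    p = np.asarray(p_kpa, dtype=float)
    return 0.622 * e / (p - 0.378 * e)


def air_density(t_c, rh_pct, p_kpa):
    """Moist air density, kg m^-3 (partial pressures of dry air and vapor)."""
    t_k = np.asarray(t_c, dtype=float) + CONST.T0
    e = vapor_pressure(t_c, rh_pct) * 1000.0       # Pa
    p = np.asarray(p_kpa, dtype=float) * 1000.0    # Pa
    return (p - e) / (CONST.Rd * t_k) + e / (CONST.Rv * t_k)


def specific_heat(t_c, rh_pct, p_kpa):
    """Specific heat of moist air, J kg^-1 K^-1."""
    q = specific_humidity(t_c, rh_pct, p_kpa)
    return CONST.cp_dry * (1.0 + 0.84 * q)


def psychrometric_constant(t_c, rh_pct, p_kpa):
    """Psychrometric constant gamma = cp P / (0.622 lambda_v), kPa K^-1."""
    cp = specific_heat(t_c, rh_pct, p_kpa)
    lam = latent_heat_vaporization(t_c)
    return cp * np.asarray(p_kpa, dtype=float) / (0.622 * lam)


def air_molar_density(t_c, p_kpa):
    """Molar density of air, mol m^-3, from the ideal gas law."""
    t_k = np.asarray(t_c, dtype=float) + CONST.T0
    return np.asarray(p_kpa, dtype=float) * 1000.0 / (CONST.R_gas * t_k)


def conductance_ms_to_mol(g_ms, t_c, p_kpa):
    """Convert conductance from m s^-1 to mol m^-2 s^-1."""
    return np.asarray(g_ms, dtype=float) * air_molar_density(t_c, p_kpa)


def conductance_mol_to_ms(g_mol, t_c, p_kpa):
    """Convert conductance from mol m^-2 s^-1 to m s^-1."""
    return np.asarray(g_mol, dtype=float) / air_molar_density(t_c, p_kpa)
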