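"""Resistance-network O3 dry deposition.

The deposition velocity Vd = Flux_O3 / [O3] (surface concentration taken as
zero) decomposes into three series resistances,

    Vd = (Ra + Rb_O3 + Rc_O3)^-1,

with Ra = u / u*^2 the aerodynamic resistance, Rb the quasi-laminar boundary
layer resistance 2/(k u*) (Sc/Pr)^(2/3), and Rc the bulk surface resistance.
Rc itself splits into parallel stomatal and non-stomatal conductances,
Rc = (Gs_O3 + Gns_O3)^-1, which is what the conductance stage estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CONST, PhysicalConstants
from . import meteo

_GAS_DIFFUSIVITY = {"O3": "D_o3", "H2O": "D_h2o"}


@dataclass
class ResistanceSet:
    """Resistances (s m^-1) and derived quantities for one half-hour."""

    Ra: float
    Rb_o3: float
    Rb_h2o: float
    Rb_heat: float
    Rc_o3: float
    Vd: float
    zeta: float
    L: float


def ppb_to_molar_density(x_ppb, t_c, p_kpa):
    """Mixing ratio (ppb) to molar density (nmol m^-3) via the ideal gas law."""
    t_c = np.asarray(t_c, dtype=float)
    p = np.asarray(p_kpa, dtype=float)
    if np.any(p <= 0) or np.any(t_c <= -100.0):
        raise ValueError("nonphysical temperature or pressure")
    n_air = meteo.air_molar_density(t_c, p)        # mol m^-3
    return np.asarray(x_ppb, dtype=float) * 1e-9 * n_air * 1e9


def deposition_velocity(flux_o3, conc_nmol_m3):
    """Vd (m s^-1) = O3 flux (nmol m^-2 s^-1) / O3 molar density (nmol m^-3).

    Negative fluxes pass through as negative Vd; callers flag them.
    """
    conc = np.asarray(conc_nmol_m3, dtype=float)
    if np.any(conc[np.isfinite(conc)] <= 0):
        raise ValueError("O3 concentration must be positive")
    return np.asarray(flux_o3, dtype=float) / conc


def aerodynamic_resistance(u, ustar):
    """Ra = u / u*^2, s m^-1 (no stability correction)."""
    ustar = np.asarray(ustar, dtype=float)
    if np.any(ustar[np.isfinite(ustar)] <= 0):
        raise ValueError("ustar must be positive")
    return np.asarray(u, dtype=float) / ustar**2


def quasilaminar_resistance(ustar, gas: str = "O3",
                            const: PhysicalConstants = CONST):
    """Rb = 2/(k u*) (Sc/Pr)^(2/3) with Sc/Pr = kappa_heat / D_gas.

    ``gas`` is one of {"O3", "H2O", "heat"}; for heat the ratio is unity.
    """
    ustar = np.asarray(ustar, dtype=float)
    if np.any(ustar[np.isfinite(ustar)] <= 0):
        raise ValueError("ustar must be positive")
    if gas == "heat":
        ratio = 1.0
    elif gas in _GAS_DIFFUSIVITY:
        ratio = const.kappa_heat / getattr(const, _GAS_DIFFUSIVITY[gas])
    else:
        raise ValueError(f"unknown gas {gas!r}")
    return 2.0 / (const.k * ustar) * ratio ** (2.0 / 3.0)


def surface_resistance(vd, ra, rb_o3):
    """Invert the series network: Rc = 1/Vd - Ra - Rb.

    Records where 1/Vd < Ra + Rb yield negative Rc; they are returned as-is
    and must be flagged/excluded downstream.
    """
    vd = np.asarray(vd, dtype=float)
    if np.any(vd[np.isfinite(vd)] <= 0):
        raise ValueError("Vd must be positive to invert the network")
    return 1.0 / vd - np.asarray(ra, dtype=float) - np.asarray(rb_o3, dtype=float)


def network_velocity(ra, rb_o3, rc_o3):
    """Forward series network: Vd = (Ra + Rb + Rc)^-1."""
    return 1.0 / (np.asarray(ra, float) + np.asarray(rb_o3, float)
                  + np.asarray(rc_o3, float))


def obukhov_stability(ustar, h, t_c, rho, r_height, canopy_height,
                      cp=None, const: PhysicalConstants = CONST):
    """Obukhov length L and stability parameter zeta = (r - d)/L.

    L = -rho cp u*^3 T_K / (k g H); d = 0.67 * canopy height. H = 0 maps to
    zeta = 0 (neutral by convention).
    """
    ustar = np.asarray(ustar, dtype=float)
    h = np.asarray(h, dtype=float)
    t_k = np.asarray(t_c, dtype=float) + CONST.T0
    rho = np.asarray(rho, dtype=float)
    cp = CONST.cp_dry if cp is None else np.asarray(cp, dtype=float)
    d = 0.67 * canopy_height
    with np.errstate(divide="ignore", invalid="ignore"):
        L = -rho * cp * ustar**3 * t_k / (const.k * const.g * h)
        zeta = np.where(h == 0, 0.0, (r_height - d) / L)
        L = np.where(h == 0, np.inf, L)
    return L, zeta


def add_deposition_columns(df: pd.DataFrame, r_height: float,
                           canopy_height: float) -> pd.DataFrame:
    """Extend a half-hourly table with VD_O3, RA, RB_O3, RC_O3, ZETA columns.

    Expects columns FO3 (nmol m^-2 s^-1), O3 (ppb), TA, RH, PA, WS, USTAR, H.
    Negative Vd or negative Rc records are flagged, not dropped.
    """
    out = df.copy()
    conc = ppb_to_molar_density(out["O3"], out["TA"], out["PA"])
    out["O3_NMOL_M3"] = conc
    with np.errstate(divide="ignore", invalid="ignore"):
        vd = out["FO3"].to_numpy() / np.where(conc > 0, conc, np.nan)
    out["VD_O3"] = vd
    ustar = out["USTAR"].to_numpy(dtype=float)
    ustar_ok = np.where(ustar > 0, ustar, np.nan)
    out["RA"] = out["WS"].to_numpy(dtype=float) / ustar_ok**2
    out["RB_O3"] = 2.0 / (CONST.k * ustar_ok) * (CONST.kappa_heat / CONST.D_o3) ** (2 / 3)
    out["RB_H2O"] = 2.0 / (CONST.k * ustar_ok) * (CONST.kappa_heat / CONST.D_h2o) ** (2 / 3)
    out["RB_HEAT"] = 2.0 / (CONST.k * ustar_ok)
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.where(vd > 0, 1.0 / vd, np.nan) - out["RA"] - out["RB_O3"]
    out["RC_O3"] = rc
    out["FLAG_VD_NEG"] = (vd <= 0) | ~np.isfinite(vd)
    out["FLAG_RC_NEG"] = np.isfinite(rc) & (rc <= 0)
    rho = meteo.air_density(out["TA"], out["RH"], out["PA"])
    cp = meteo.specific_heat(out["TA"], out["RH"], out["PA"])
    out["RHO"] = rho
    out["CP"] = cp
    _, zeta = obukhov_stability(ustar_ok, out["H"], out["TA"], rho,
                                r_height, canopy_height, cp=cp)
    out["ZETA"] = zeta
    return out
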