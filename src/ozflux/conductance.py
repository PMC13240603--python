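"""Stomatal conductance two ways: Penman-Monteith inversion and Medlyn fits.

The PM route inverts the evaporation-resistance form of the Penman-Monteith
equation for the bulk surface resistance to water vapor,

    Rc_H2O = rho cp VPDcan / (gamma lambdaE) - Ra - Rb_H2O,

using the canopy-to-air vapor pressure deficit VPDcan = es(Ts) - e_r with a
surface temperature diagnosed from the sensible heat flux,
Ts = Tair + H (Ra + Rb_heat)/(rho cp). After filtering to dry, daytime,
low-RH conditions the surface conductance 1/Rc is read as stomatal
conductance Gs_H2O_PM.

The Medlyn route models stomatal conductance from gross primary productivity,

    Gs_H2O_MED = G0 + 1.6 (1 + G1/VPDcan) GPP/Ca,

with (G0, G1) fitted to the PM estimates by nonlinear least squares in
10-day windows (>= 20 valid half-hours per window). Both estimates convert
to O3 conductances through the 0.61 diffusivity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import CONST
from . import meteo
from .meteo import saturation_vapor_pressure
from .solar import solar_position

# exclusion reason codes for the validity mask
REASON_RAIN = "rain_window"
REASON_SZA = "sza"
REASON_RH = "rh"
REASON_RATIO = "ratio"
REASON_PM_INVALID = "pm_invalid"


def surface_temperature(t_air, h, rho, cp, ra, rb_heat):
    """Surface (big-leaf) temperature from the sensible heat flux.

    Ts = Tair + H (Ra + Rb_heat) / (rho cp), degC.
    """
    ra = np.asarray(ra, dtype=float)
    rb_heat = np.asarray(rb_heat, dtype=float)
    if np.any(ra[np.isfinite(ra)] < 0) or np.any(rb_heat[np.isfinite(rb_heat)] < 0):
        raise ValueError("resistances must be positive")
    return (np.asarray(t_air, float)
            + np.asarray(h, float) * (ra + rb_heat)
            / (np.asarray(rho, float) * np.asarray(cp, float)))


def canopy_vpd(t_s, e_r):
    """Canopy-to-air VPD (kPa): es(Ts) - e_r; negative values mean dew-like
    conditions and are flagged by callers, not clipped here."""
    e_r = np.asarray(e_r, dtype=float)
    if np.any(e_r[np.isfinite(e_r)] < 0):
        raise ValueError("vapor pressure must be non-negative")
    return saturation_vapor_pressure(t_s) - e_r


def pm_inversion(lam_e, vpd_can, gamma, rho, cp, ra, rb_h2o):
    """Invert Penman-Monteith for surface conductance to water vapor (m s^-1).

    Returns (conductance, valid): records with lambdaE <= 0, VPDcan <= 0 or a
    non-positive inverted resistance come back NaN with valid=False.
    """
    lam_e = np.asarray(lam_e, dtype=float)
    vpd_can = np.asarray(vpd_can, dtype=float)
    ok = np.isfinite(lam_e) & np.isfinite(vpd_can) & (lam_e > 0) & (vpd_can > 0)
    rc = np.full(np.broadcast(lam_e, vpd_can).shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rc_all = (np.asarray(rho, float) * np.asarray(cp, float) * vpd_can
                  / (np.asarray(gamma, float) * lam_e)
                  - np.asarray(ra, float) - np.asarray(rb_h2o, float))
    rc = np.where(ok, rc_all, np.nan)
    valid = ok & np.isfinite(rc) & (rc > 0)
    g = np.where(valid, 1.0 / np.where(valid, rc, np.nan), np.nan)
    return g, valid


def h2o_to_o3_conductance(gs_h2o):
    """Scale an H2O conductance to O3 by the diffusivity ratio 0.61."""
    return CONST.D_ratio_o3_h2o * np.asarray(gs_h2o, dtype=float)


def rain_window_mask(times: pd.DatetimeIndex, precip: np.ndarray,
                     window_h: float = 36.0) -> np.ndarray:
    """True where the record falls in a rain event or within ``window_h``
    hours after one."""
    times = pd.DatetimeIndex(times)
    precip = np.asarray(precip, dtype=float)
    wet = np.zeros(len(times), dtype=bool)
    rain_times = times[np.nan_to_num(precip) > 0]
    if len(rain_times) == 0:
        return wet
    # half-hourly cadence: expand each event into the following window
    window = pd.Timedelta(hours=window_h)
    t = times.to_numpy()
    for rt in rain_times.to_numpy():
        wet |= (t >= rt) & (t <= rt + window)
    return wet


def stomatal_validity_mask(df: pd.DataFrame, lat: float, lon: float,
                           utc_offset: float, rain_window_h: float = 36.0,
                           rh_max: float = 80.0, sza_max: float = 85.0):
    """Validity mask for treating PM surface conductance as stomatal.

    A record is valid iff it is outside a rain event and its trailing window,
    the solar zenith angle is < sza_max, and RH < rh_max (both strict).
    Returns (mask, reasons DataFrame of per-reason boolean exclusions).
    """
    times = pd.DatetimeIndex(df["TIMESTAMP"])
    zen = solar_position(times, lat, lon, utc_offset)["zenith"].to_numpy()
    wet = rain_window_mask(times, df["P"].to_numpy(), rain_window_h)
    rh = df["RH"].to_numpy(dtype=float)
    reasons = pd.DataFrame({
        REASON_RAIN: wet,
        REASON_SZA: zen >= sza_max,
        REASON_RH: rh >= rh_max,
    }, index=df.index)
    mask = ~reasons.any(axis=1)
    return mask.to_numpy(), reasons


@dataclass
class MedlynFit:
    """One fitted window of the Medlyn stomatal conductance model."""

    start: pd.Timestamp
    end: pd.Timestamp
    g0: float           # mol m^-2 s^-1
    g1: float           # kPa
    n_obs: int
    converged: bool
    resid_scale: float  # RMS residual, mol m^-2 s^-1


def medlyn_model(gpp, vpd_can, g0, g1, ca_umol=420.0, sqrt_vpd=False):
    """Gs_H2O (mol m^-2 s^-1) = G0 + 1.6 (1 + G1/VPDcan) GPP/Ca.

    GPP in umol m^-2 s^-1, Ca in umol mol^-1, VPDcan in kPa. The
    ``sqrt_vpd`` switch uses G1/sqrt(VPDcan) (the original leaf-level form).
    """
    gpp = np.asarray(gpp, dtype=float)
    vpd_can = np.asarray(vpd_can, dtype=float)
    v = np.sqrt(vpd_can) if sqrt_vpd else vpd_can
    return g0 + 1.6 * (1.0 + g1 / v) * gpp / ca_umol


def fit_medlyn(gs_mol, gpp, vpd_can, ca_umol=420.0, sqrt_vpd=False):
    """Nonlinear least-squares fit of (G0, G1) with bounds G0, G1 >= 0.

    Returns (g0, g1, converged, rms_residual).
    """
    gs_mol = np.asarray(gs_mol, dtype=float)
    gpp = np.asarray(gpp, dtype=float)
    vpd_can = np.asarray(vpd_can, dtype=float)

    def f(x, g0, g1):
        gpp_x, vpd_x = x
        return medlyn_model(gpp_x, vpd_x, g0, g1, ca_umol, sqrt_vpd)

    try:
        popt, _ = curve_fit(f, (gpp, vpd_can), gs_mol, p0=(0.01, 2.0),
                            bounds=([0.0, 0.0], [np.inf, np.inf]),
                            maxfev=10000)
    except RuntimeError:
        return np.nan, np.nan, False, np.nan
    resid = gs_mol - f((gpp, vpd_can), *popt)
    return float(popt[0]), float(popt[1]), True, float(np.sqrt(np.mean(resid**2)))


def fit_medlyn_windows(df: pd.DataFrame, window_days: int = 10,
                       min_obs: int = 20, ca_umol: float = 420.0,
                       sqrt_vpd: bool = False,
                       season_wide: bool = False) -> list[MedlynFit]:
    """Fit (G0, G1) in consecutive windows of ``window_days`` days.

    ``df`` must hold mask-valid records only, with columns GS_H2O_PM_MOL,
    GPP, VPD_CAN and TIMESTAMP. Windows align to the first valid date.
    Windows with fewer than ``min_obs`` observations emit no fit. With
    ``season_wide`` a single fit over all records is returned instead.
    """
    df = df.dropna(subset=["GS_H2O_PM_MOL", "GPP", "VPD_CAN"])
    if df.empty:
        return []
    times = pd.DatetimeIndex(df["TIMESTAMP"])
    if season_wide:
        groups = [(times.min().normalize(),
                   times.max().normalize() + pd.Timedelta(days=1), df)]
    else:
        t0 = times.min().normalize()
        idx = ((times - t0).days // window_days).astype(int)
        groups = []
        for w in np.unique(idx):
            sub = df[idx == w]
            groups.append((t0 + pd.Timedelta(days=int(w) * window_days),
                           t0 + pd.Timedelta(days=(int(w) + 1) * window_days),
                           sub))
    fits: list[MedlynFit] = []
    for start, end, sub in groups:
        if len(sub) < min_obs:
            continue
        g0, g1, conv, rms = fit_medlyn(sub["GS_H2O_PM_MOL"], sub["GPP"],
                                       sub["VPD_CAN"], ca_umol, sqrt_vpd)
        fits.append(MedlynFit(start, end, g0, g1, len(sub), conv, rms))
    return [f for f in fits if f.converged]


def medlyn_predict(fits: Sequence[MedlynFit], times: pd.DatetimeIndex,
                   gpp, vpd_can, ca_umol=420.0, sqrt_vpd=False):
    """Evaluate windowed fits at each record (mol m^-2 s^-1).

    Records outside any fitted window, or with VPDcan <= 0, come back NaN.
    """
    times = pd.DatetimeIndex(times)
    gpp = np.asarray(gpp, dtype=float)
    vpd_can = np.asarray(vpd_can, dtype=float)
    out = np.full(len(times), np.nan)
    for f in fits:
        sel = (times >= f.start) & (times < f.end) & (vpd_can > 0)
        out[sel] = medlyn_model(gpp[sel], vpd_can[sel], f.g0, f.g1,
                                ca_umol, sqrt_vpd)
    return out


def add_conductance_columns(df: pd.DataFrame, lat: float, lon: float,
                            utc_offset: float, rain_window_h: float = 36.0,
                            rh_max: float = 80.0, sza_max: float = 85.0,
                            ca_umol: float = 420.0, sqrt_vpd: bool = False,
                            season_wide: bool = False,
                            min_obs: int = 20):
    """Run the full conductance stage on a deposition-extended table.

    Adds TS, VPD_CAN, GS_H2O_PM (m s^-1), GS_H2O_PM_MOL, GS_O3_PM, GS_O3_MED,
    GC_O3, RATIO_PM, RATIO_MED and VALID_* columns; returns
    (table, fits, exclusion_counts).
    """
    out = df.copy()
    rho, cp = out["RHO"], out["CP"]
    gamma = meteo.psychrometric_constant(out["TA"], out["RH"], out["PA"])
    e_r = meteo.vapor_pressure(out["TA"], out["RH"])
    ts = surface_temperature(out["TA"], out["H"], rho, cp,
                             out["RA"], out["RB_HEAT"])
    vpd_can = canopy_vpd(ts, e_r)
    out["TS"] = ts
    out["VPD_CAN"] = vpd_can

    gs_pm_ms, pm_valid = pm_inversion(out["LE"], vpd_can, gamma, rho, cp,
                                      out["RA"], out["RB_H2O"])
    out["GS_H2O_PM"] = gs_pm_ms
    out["GS_H2O_PM_MOL"] = meteo.conductance_ms_to_mol(gs_pm_ms, out["TA"], out["PA"])
    out["GS_O3_PM"] = h2o_to_o3_conductance(gs_pm_ms)

    mask, reasons = stomatal_validity_mask(out, lat, lon, utc_offset,
                                           rain_window_h, rh_max, sza_max)
    reasons[REASON_PM_INVALID] = ~pm_valid
    valid = mask & pm_valid
    out["VALID_STOMATAL"] = valid

    # Gc_O3 from the measured network; ratio filter closed interval [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_o3 = np.where(out["RC_O3"] > 0, 1.0 / out["RC_O3"], np.nan)
    out["GC_O3"] = gc_o3
    ratio_pm = out["GS_O3_PM"] / gc_o3
    out["RATIO_PM"] = ratio_pm

    fit_df = out.loc[valid, ["TIMESTAMP", "GS_H2O_PM_MOL", "GPP", "VPD_CAN"]]
    fits = fit_medlyn_windows(fit_df, min_obs=min_obs, ca_umol=ca_umol,
                              sqrt_vpd=sqrt_vpd, season_wide=season_wide)
    gs_med_mol = medlyn_predict(fits, pd.DatetimeIndex(out["TIMESTAMP"]),
                                out["GPP"], out["VPD_CAN"], ca_umol, sqrt_vpd)
    out["GS_H2O_MED_MOL"] = gs_med_mol
    gs_med_ms = meteo.conductance_mol_to_ms(gs_med_mol, out["TA"], out["PA"])
    out["GS_H2O_MED"] = gs_med_ms
    out["GS_O3_MED"] = h2o_to_o3_conductance(gs_med_ms)
    out["RATIO_MED"] = out["GS_O3_MED"] / gc_o3

    for which in ("PM", "MED"):
        r = out[f"RATIO_{which}"]
        ok = valid & np.isfinite(r) & (r >= 0.0) & (r <= 1.0)
        out[f"VALID_{which}"] = ok
    reasons[REASON_RATIO] = (valid
                             & ~(out["VALID_PM"] | out["VALID_MED"]))
    counts = reasons.sum().to_dict()
    return out, fits, counts
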