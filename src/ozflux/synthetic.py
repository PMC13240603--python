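"""Synthetic big-leaf world with known ground truth.

The generator emulates a peak-season maize tower: diurnal shortwave,
temperature and humidity cycles with Poisson rain events; an
afternoon-peaking O3 mixing-ratio cycle; GPP from a rectangular-hyperbola
light response; Lloyd-Taylor respiration; stomatal conductance from the
Medlyn model with known (G0, G1); a known non-stomatal O3 conductance; and
the full resistance network run forward to O3 flux, latent and sensible
heat. Observation noise is Gaussian (multiplicative on fluxes, additive on
temperature). Hidden truth goes to a sidecar table, never the observation
file.

Because the forward model evaluates the same Penman-Monteith, resistance
and Medlyn expressions the analysis inverts - with the canopy VPD solved to
a self-consistent fixed point - a noiseless season round-trips through the
pipeline to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CONST
from . import meteo
from .conductance import medlyn_model, surface_temperature, canopy_vpd
from .deposition import ppb_to_molar_density
from .ecflux import HighFrequencyBlock, SAMPLES_PER_BLOCK
from .io import SiteMeta
from .partition import lloyd_taylor
from .solar import solar_position

DEFAULT_NOISE = {"flux": 0.05, "ta": 0.2, "o3": 0.05}


@dataclass
class TruthParams:
    """Ground-truth parameters of the synthetic world."""

    G0_true: float = 0.02       # residual conductance, mol m^-2 s^-1
    G1_true: float = 3.0        # Medlyn slope, kPa
    Gns_true: float = 0.002     # non-stomatal O3 conductance, m s^-1
    amax: float = 55.0          # light-saturated GPP, umol m^-2 s^-1
    alpha_q: float = 0.06       # initial light-use slope (per W m^-2 here)
    t_sens: float = 0.08        # C4 GPP temperature sensitivity, K^-1 about 22 degC
    Rref: float = 2.0           # base respiration, umol m^-2 s^-1
    E0: float = 200.0           # temperature sensitivity, K
    o3_base: float = 25.0       # ppb
    o3_amp: float = 25.0        # afternoon-peak amplitude, ppb
    o3_peak_hour: float = 14.0  # decimal hour
    rain_rate: float = 0.2      # events day^-1
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.G0_true, self.G1_true, self.Gns_true) < 0:
            raise ValueError("conductance parameters must be >= 0")
        if self.amax <= 0:
            raise ValueError("amax must be positive")
        if self.o3_base < 0:
            raise ValueError("o3_base must be >= 0")
        if any(not (0.0 <= v < 1.0) for k, v in self.noise_sd.items()
               if k != "ta"):
            raise ValueError("relative noise fractions must lie in [0, 1)")


def gen_meteorology(days: int, params: TruthParams,
                    site: SiteMeta | None = None,
                    start: str = "2023-07-01") -> pd.DataFrame:
    """Half-hourly meteorological drivers for ``days`` days.

    Clear-sky shortwave follows the solar elevation, scaled by a per-day
    random cloud factor; air temperature lags shortwave with an afternoon
    peak; RH moves opposite temperature; rain events arrive as a Poisson
    process, dim the sun and push RH up. Deterministic given the seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    site = site or SiteMeta()
    rng = np.random.default_rng(params.seed)
    n = days * 48
    times = pd.date_range(pd.Timestamp(start) + pd.Timedelta(minutes=30),
                          periods=n, freq="30min")
    pos = solar_position(times, site.latitude, site.longitude, site.utc_offset)
    elev = np.deg2rad(np.maximum(pos["elevation"].to_numpy(), 0.0))
    sw_clear = 1000.0 * np.sin(elev)

    day_idx = np.repeat(np.arange(days), 48)
    cloud = rng.uniform(0.55, 1.0, size=days)[day_idx]

    # precipitation: Poisson event count, events placed uniformly in time
    n_events = rng.poisson(params.rain_rate * days)
    precip = np.zeros(n)
    event_slots = rng.integers(0, n, size=n_events)
    precip[event_slots] += rng.exponential(5.0, size=n_events)
    wet = precip > 0
    # rain dims the sun for the wet half-hour and raises RH for 6 h after
    rain_recent = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(wet):
        rain_recent[i:i + 12] = True
    cloud = np.where(wet, 0.15, cloud)
    hod = (times.hour + times.minute / 60.0).to_numpy()
    # humid-morning haze: the summertime boundary layer attenuates morning
    # shortwave and burns off toward midday, skewing radiation afternoon-ward
    haze = 1.0 - 0.25 * np.exp(-0.5 * ((hod - 8.0) / 2.0) ** 2)
    sw_in = sw_clear * cloud * haze
    t_daily = 22.0 + rng.normal(0.0, 2.0, size=days)[day_idx]
    tair = t_daily + 6.0 * np.cos(2 * np.pi * (hod - 15.0) / 24.0)
    rh = np.clip(78.0 - 2.2 * (tair - t_daily) - 6.0 * (cloud - 0.8), 30.0, 100.0)
    rh = np.where(rain_recent, np.minimum(rh + 18.0, 100.0), rh)

    # calm nights, breezier days: nocturnal u* spans the weak-turbulence
    # regime where the friction-velocity screen operates
    ws = (0.55 + 2.8 * np.sin(elev)) * rng.lognormal(0.0, 0.35, size=n)
    ustar = 0.17 * ws

    return pd.DataFrame({
        "TIMESTAMP": times, "SW_IN": sw_in, "TA": tair, "RH": rh,
        "PA": np.full(n, 101.325), "P": precip, "WS": ws, "USTAR": ustar,
    })


def _forward_surface(meteo_df: pd.DataFrame, params: TruthParams,
                     site: SiteMeta, n_iter: int = 60):
    """Solve the coupled Medlyn / Penman-Monteith / energy-balance forward
    model for a self-consistent canopy state. Returns a dict of truth arrays.
    """
    ta = meteo_df["TA"].to_numpy()
    rh = meteo_df["RH"].to_numpy()
    pa = meteo_df["PA"].to_numpy()
    ws = meteo_df["WS"].to_numpy()
    ustar = meteo_df["USTAR"].to_numpy()
    sw = meteo_df["SW_IN"].to_numpy()

    rho = meteo.air_density(ta, rh, pa)
    cp = meteo.specific_heat(ta, rh, pa)
    gamma = meteo.psychrometric_constant(ta, rh, pa)
    e_r = meteo.vapor_pressure(ta, rh)
    n_air = meteo.air_molar_density(ta, pa)

    ra = ws / ustar**2
    rb_h2o = 2.0 / (CONST.k * ustar) * (CONST.kappa_heat / CONST.D_h2o) ** (2 / 3)
    rb_o3 = 2.0 / (CONST.k * ustar) * (CONST.kappa_heat / CONST.D_o3) ** (2 / 3)
    rb_heat = 2.0 / (CONST.k * ustar)

    # rectangular-hyperbola light response with a mild C4 temperature
    # modifier: warm afternoons sustain photosynthesis (and so conductance)
    gpp = params.amax * params.alpha_q * sw / (params.amax + params.alpha_q * sw)
    gpp = gpp * np.maximum(0.0, 1.0 + params.t_sens * (ta - 22.0))
    reco = lloyd_taylor(ta, params.Rref, params.E0)
    avail = 0.65 * sw - 20.0        # available energy A = H + lambdaE

    vpd_can = meteo.vpd(ta, rh)
    lam_e = np.zeros_like(ta)
    for _ in range(n_iter):
        vpd_pos = np.maximum(vpd_can, 0.01)
        gs_mol = medlyn_model(gpp, vpd_pos, params.G0_true, params.G1_true)
        gs_ms = gs_mol / n_air
        rc_h2o = 1.0 / gs_ms
        lam_e_new = rho * cp * np.maximum(vpd_can, 0.0) \
            / (gamma * (ra + rb_h2o + rc_h2o))
        lam_e = 0.5 * lam_e + 0.5 * lam_e_new
        h = avail - lam_e
        ts = surface_temperature(ta, h, rho, cp, ra, rb_heat)
        vpd_can = canopy_vpd(ts, e_r)

    vpd_pos = np.maximum(vpd_can, 0.01)
    gs_mol = medlyn_model(gpp, vpd_pos, params.G0_true, params.G1_true)
    gs_ms = gs_mol / n_air
    lam_e = rho * cp * np.maximum(vpd_can, 0.0) / (gamma * (ra + rb_h2o + 1.0 / gs_ms))
    h = avail - lam_e

    gs_o3 = CONST.D_ratio_o3_h2o * gs_ms
    gc_o3 = gs_o3 + params.Gns_true
    rc_o3 = 1.0 / gc_o3
    vd = 1.0 / (ra + rb_o3 + rc_o3)
    return {
        "gpp": gpp, "reco": reco, "nee": reco - gpp,
        "gs_mol": gs_mol, "gs_ms": gs_ms, "gs_o3": gs_o3, "gc_o3": gc_o3,
        "vd": vd, "lam_e": lam_e, "h": h, "ts": ts, "vpd_can": vpd_can,
        "ra": ra, "rb_o3": rb_o3, "frac": gs_o3 / gc_o3,
    }


def _o3_cycle(times: pd.DatetimeIndex, params: TruthParams,
              rng: np.random.Generator) -> np.ndarray:
    """Afternoon-peaking Gaussian-bump O3 mixing ratio (ppb), floored at 0,
    with mild day-to-day variability."""
    hod = (times.hour + times.minute / 60.0).to_numpy()
    days = times.normalize()
    uniq = days.unique()
    day_factor = pd.Series(rng.uniform(0.8, 1.2, size=len(uniq)),
                           index=uniq).reindex(days).to_numpy()
    bump = params.o3_amp * np.exp(-0.5 * ((hod - params.o3_peak_hour) / 3.0) ** 2)
    return np.maximum(0.0, (params.o3_base + bump) * day_factor)


def gen_halfhourly_truth(meteo_df: pd.DataFrame, params: TruthParams,
                         site: SiteMeta | None = None,
                         ustar_suppress: float | None = None):
    """Forward-model a half-hourly season; return (observations, truth).

    Observations carry AmeriFlux-style columns (TIMESTAMP_START/END, SW_IN,
    TA, RH, PA, P, WS, USTAR, H, LE, FC, O3, FO3) with Gaussian noise per
    ``params.noise_sd``; the truth sidecar holds every hidden state.
    ``ustar_suppress`` optionally damps observed nighttime FC below the
    given friction-velocity threshold (weak-turbulence bias emulation).
    """
    site = site or SiteMeta()
    rng = np.random.default_rng(params.seed + 1)
    times = pd.DatetimeIndex(meteo_df["TIMESTAMP"])
    truth = _forward_surface(meteo_df, params, site)

    o3_ppb = _o3_cycle(times, params, rng)
    conc = ppb_to_molar_density(o3_ppb, meteo_df["TA"], meteo_df["PA"])
    fo3 = truth["vd"] * conc        # nmol m^-2 s^-1

    ns = params.noise_sd
    n = len(times)

    def mult(x, key):
        f = ns.get(key, 0.0)
        return x * (1.0 + f * rng.standard_normal(n)) if f else x

    ta_obs = meteo_df["TA"].to_numpy() + ns.get("ta", 0.0) * rng.standard_normal(n) \
        if ns.get("ta", 0.0) else meteo_df["TA"].to_numpy()
    nee_obs = mult(truth["nee"], "flux")
    if ustar_suppress is not None:
        elev = solar_position(times, site.latitude, site.longitude,
                              site.utc_offset)["elevation"].to_numpy()
        night = elev <= 0
        damp = np.clip(meteo_df["USTAR"].to_numpy() / ustar_suppress, 0.0, 1.0)
        nee_obs = np.where(night, nee_obs * damp, nee_obs)

    ts_start = times - pd.Timedelta(minutes=30)
    obs = pd.DataFrame({
        "TIMESTAMP_START": ts_start.strftime("%Y%m%d%H%M").astype("int64"),
        "TIMESTAMP_END": times.strftime("%Y%m%d%H%M").astype("int64"),
        "SW_IN": meteo_df["SW_IN"].to_numpy(),
        "TA": ta_obs, "RH": meteo_df["RH"].to_numpy(),
        "PA": meteo_df["PA"].to_numpy(), "P": meteo_df["P"].to_numpy(),
        "WS": meteo_df["WS"].to_numpy(), "USTAR": meteo_df["USTAR"].to_numpy(),
        "H": mult(truth["h"], "flux"), "LE": mult(truth["lam_e"], "flux"),
        "FC": nee_obs, "O3": mult(o3_ppb, "o3"), "FO3": mult(fo3, "flux"),
    })
    obs["TIMESTAMP"] = times

    truth_df = pd.DataFrame({
        "TIMESTAMP_START": obs["TIMESTAMP_START"],
        "TIMESTAMP_END": obs["TIMESTAMP_END"],
        "GPP_TRUE": truth["gpp"], "RECO_TRUE": truth["reco"],
        "NEE_TRUE": truth["nee"],
        "GS_H2O_MOL_TRUE": truth["gs_mol"], "GS_H2O_MS_TRUE": truth["gs_ms"],
        "GS_O3_TRUE": truth["gs_o3"], "GC_O3_TRUE": truth["gc_o3"],
        "GNS_O3_TRUE": np.full(n, params.Gns_true),
        "VD_TRUE": truth["vd"], "FO3_TRUE": fo3,
        "FRAC_STOM_TRUE": truth["frac"],
        "VPD_CAN_TRUE": truth["vpd_can"], "TS_TRUE": truth["ts"],
        "LE_TRUE": truth["lam_e"], "H_TRUE": truth["h"], "O3_TRUE": o3_ppb,
    })
    truth_df["TIMESTAMP"] = times
    return obs, truth_df


def gen_highfreq_block(cov_ws: float, tilt_deg: float = 0.0,
                       spike_frac: float = 0.0, missing_frac: float = 0.0,
                       seed: int = 0, mean_u: float = 2.0,
                       sigma_w: float = 0.4, sigma_s: float = 2.0,
                       n: int = SAMPLES_PER_BLOCK) -> HighFrequencyBlock:
    """One 30-min 10 Hz block of correlated Gaussian (w, scalar) turbulence.

    (w, s) are drawn with population covariance ``cov_ws``; the wind vector
    is then tilted by ``tilt_deg`` in the u-w plane (sonic misalignment),
    and spikes / missing values injected at the requested fractions. The
    scalar is stored on the O3 channel.
    """
    if abs(tilt_deg) >= 30.0:
        raise ValueError("|tilt| must be < 30 deg")
    for frac in (spike_frac, missing_frac):
        if not 0.0 <= frac <= 0.5:
            raise ValueError("fractions must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    rho_ws = cov_ws / (sigma_w * sigma_s)
    if abs(rho_ws) > 1:
        raise ValueError("cov_ws incompatible with channel variances")
    cov = np.array([[sigma_w**2, cov_ws], [cov_ws, sigma_s**2]])
    wz, s = rng.multivariate_normal([0.0, 20.0], cov, size=n).T
    u = mean_u + 0.5 * rng.standard_normal(n)
    v = 0.3 * rng.standard_normal(n)
    # downward momentum flux (cov_uw ~ -0.095) so sigma_w/u* sits near the
    # neutral surface-layer value and the block passes the ITC test
    w = wz - 0.38 * (u - mean_u)
    # tilt: rotate (u, w) by tilt_deg as if the sonic were pitched
    th = np.deg2rad(tilt_deg)
    u_t = u * np.cos(th) - w * np.sin(th)
    w_t = u * np.sin(th) + w * np.cos(th)

    if spike_frac > 0:
        k = int(round(spike_frac * n))
        idx = rng.choice(n, size=k, replace=False)
        w_t[idx] += rng.choice([-1, 1], size=k) * 20.0 * sigma_w
    if missing_frac > 0:
        k = int(round(missing_frac * n))
        idx = rng.choice(n, size=k, replace=False)
        w_t[idx] = np.nan

    t = np.arange(n) / 10.0
    return HighFrequencyBlock(t=t, u=u_t, v=v, w=w_t,
                              Ts=20.0 + 0.5 * rng.standard_normal(n),
                              c_o3=s)
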