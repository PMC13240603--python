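"""Half-hourly fluxes from 10 Hz sonic/gas-analyzer blocks.

Processing per 30-min block: moving-window median/MAD despiking, double
rotation of the wind vector (mean v and mean w forced to zero), covariance
fluxes of deviations from the block mean,

    Flux_s = cov(w, s)         (gas flux, units of s * m s^-1)
    H      = rho cp cov(w, T)
    lambdaE = lambda_v M_H2O Flux_H2O * 1e-6   (umol -> mol conversion)
    u*     = (cov(u,w)^2 + cov(v,w)^2)^(1/4)

plus steady-state and integral-turbulence-characteristics (SSITC) quality
classes, and a screen dropping half-hours with > 10% missing samples or
SSITC class 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CONST

SAMPLES_PER_BLOCK = 18000       # 10 Hz x 1800 s
DESPIKE_WINDOW = 3000           # 5 min at 10 Hz
ITC_NEUTRAL_SIGW_USTAR = 1.3    # neutral-limit sigma_w / u*


@dataclass
class HighFrequencyBlock:
    """One 30-min block of 10 Hz samples (NaN marks missing)."""

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    Ts: np.ndarray
    c_co2: np.ndarray | None = None
    c_h2o: np.ndarray | None = None
    c_o3: np.ndarray | None = None

    def missing_fraction(self, channel: str) -> float:
        x = getattr(self, channel)
        return float(np.mean(~np.isfinite(x)))


@dataclass
class FluxRecord:
    """Half-hourly covariance fluxes with quality flags."""

    timestamp: pd.Timestamp
    flux_o3: float          # nmol m^-2 s^-1
    flux_co2: float         # umol m^-2 s^-1
    flux_h2o: float         # umol m^-2 s^-1 (molar), mirrors lambdaE
    H: float                # W m^-2
    lamE: float             # W m^-2
    ustar: float            # m s^-1
    missing_frac: float
    ss_class: int = 0
    itc_class: int = 0
    valid: bool = True
    extras: dict = field(default_factory=dict)


def despike(samples, k_mad: float = 6.0, window: int = DESPIKE_WINDOW):
    """Mask spikes beyond k_mad moving-window MADs from the moving median.

    Returns (masked copy with spikes set to NaN, removed count). MAD of an
    exactly-constant window is 0; such windows remove nothing.
    """
    x = pd.Series(np.asarray(samples, dtype=float))
    if x.notna().sum() == 0:
        raise ValueError("all samples missing")
    med = x.rolling(window, center=True, min_periods=1).median()
    mad = (x - med).abs().rolling(window, center=True, min_periods=1).median()
    dev = (x - med).abs()
    spikes = (dev > k_mad * mad) & (mad > 0) & x.notna()
    out = x.to_numpy().copy()
    out[spikes.to_numpy()] = np.nan
    return out, int(spikes.sum())


def double_rotation(u, v, w):
    """Rotate wind into the mean streamline frame (mean v = mean w = 0).

    First a yaw rotation aligns the x-axis with the mean horizontal wind,
    then a pitch rotation zeroes the mean vertical velocity. Per-sample
    vector magnitude is preserved. Returns (u_r, v_r, w_r, yaw, pitch) with
    angles in radians.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    ok = np.isfinite(u) & np.isfinite(v) & np.isfinite(w)
    if ok.sum() < 2:
        raise ValueError("need at least 2 valid samples")
    um, vm, wm = u[ok].mean(), v[ok].mean(), w[ok].mean()
    if um == 0 and vm == 0 and wm == 0:
        raise ValueError("degenerate all-zero mean wind")
    yaw = np.arctan2(vm, um)
    u1 = u * np.cos(yaw) + v * np.sin(yaw)
    v1 = -u * np.sin(yaw) + v * np.cos(yaw)
    pitch = np.arctan2(wm, np.hypot(um, vm))
    u2 = u1 * np.cos(pitch) + w * np.sin(pitch)
    w2 = -u1 * np.sin(pitch) + w * np.cos(pitch)
    return u2, v1, w2, float(yaw), float(pitch)


def _cov(a, b):
    """Covariance of deviations from the block mean over jointly valid samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    ad = a[ok] - a[ok].mean()
    bd = b[ok] - b[ok].mean()
    return float(np.mean(ad * bd))


def block_fluxes(block: HighFrequencyBlock, rho: float, cp: float,
                 t_air_c: float | None = None,
                 literal_eq3: bool = False,
                 timestamp=None) -> FluxRecord:
    """Covariance fluxes for one despiked, rotated block.

    ``rho``/``cp`` describe the half-hour air state; sonic temperature is
    used for the heat flux without humidity correction. ``literal_eq3``
    applies a 1e-3 factor in lambdaE instead of the unit-exact 1e-6.
    """
    cov_uw = _cov(block.u, block.w)
    cov_vw = _cov(block.v, block.w)
    cov_wT = _cov(block.w, block.Ts)
    ustar = (cov_uw**2 + cov_vw**2) ** 0.25
    H = rho * cp * cov_wT

    t_c = float(np.nanmean(block.Ts)) if t_air_c is None else t_air_c
    lam = (2.501 - 0.00237 * t_c) * 1e6
    flux_h2o = _cov(block.w, block.c_h2o) if block.c_h2o is not None else np.nan
    conv = 1e-3 if literal_eq3 else 1e-6
    lamE = lam * CONST.M_h2o * flux_h2o * conv if np.isfinite(flux_h2o) else np.nan
    flux_co2 = _cov(block.w, block.c_co2) if block.c_co2 is not None else np.nan
    flux_o3 = _cov(block.w, block.c_o3) if block.c_o3 is not None else np.nan

    missing = max(block.missing_fraction(c)
                  for c in ("u", "v", "w", "Ts"))
    return FluxRecord(timestamp=timestamp, flux_o3=flux_o3, flux_co2=flux_co2,
                      flux_h2o=flux_h2o, H=H, lamE=lamE, ustar=float(ustar),
                      missing_frac=missing)


def steady_state_class(w, s, n_sub: int = 6) -> int:
    """Foken-style stationarity class from 5-min sub-covariances.

    Relative deviation of the mean sub-block covariance from the whole-block
    covariance: <= 30% class 0, <= 100% class 1, else class 2.
    """
    w = np.asarray(w, dtype=float)
    s = np.asarray(s, dtype=float)
    n = len(w)
    if n < 2 * n_sub:
        raise ValueError("too few samples for sub-intervals")
    edges = np.linspace(0, n, n_sub + 1, dtype=int)
    subs = [_cov(w[a:b], s[a:b]) for a, b in zip(edges[:-1], edges[1:])]
    whole = _cov(w, s)
    if whole == 0 or not np.isfinite(whole):
        return 2
    rel = abs((np.nanmean(subs) - whole) / whole)
    if rel <= 0.30:
        return 0
    if rel <= 1.00:
        return 1
    return 2


def itc_class(w, ustar: float,
              model_ratio: float = ITC_NEUTRAL_SIGW_USTAR) -> int:
    """Integral-turbulence-characteristics class from sigma_w / u*.

    Relative deviation from the neutral-limit model value, same class bands
    as the steady-state test.
    """
    w = np.asarray(w, dtype=float)
    sigw = float(np.nanstd(w[np.isfinite(w)]))
    if ustar <= 0 or not np.isfinite(ustar):
        return 2
    rel = abs(sigw / ustar - model_ratio) / model_ratio
    if rel <= 0.30:
        return 0
    if rel <= 1.00:
        return 1
    return 2


def ssitc_flags(block: HighFrequencyBlock, scalar: str = "Ts") -> tuple[int, int]:
    """(steady-state class, ITC class) for one block against scalar channel."""
    s = getattr(block, scalar)
    ss = steady_state_class(block.w, s)
    cov_uw = _cov(block.u, block.w)
    cov_vw = _cov(block.v, block.w)
    ustar = (cov_uw**2 + cov_vw**2) ** 0.25
    return ss, itc_class(block.w, ustar)


def qc_screen(records: list[FluxRecord], max_missing: float = 0.10):
    """Drop half-hours with missing fraction > 10% or SSITC class 2.

    The 10% rule is inclusive ("no more than 10%"): exactly 0.10 is kept.
    Returns (retained, bookkeeping dict of removal counts).
    """
    kept, n_missing, n_ssitc = [], 0, 0
    for r in records:
        if r.missing_frac > max_missing:
            n_missing += 1
            continue
        if r.ss_class == 2 or r.itc_class == 2:
            n_ssitc += 1
            continue
        kept.append(r)
    return kept, {"removed_missing": n_missing, "removed_ssitc": n_ssitc,
                  "records_in": len(records), "records_out": len(kept)}


def process_block(block: HighFrequencyBlock, rho: float, cp: float,
                  k_mad: float = 6.0, timestamp=None,
                  literal_eq3: bool = False) -> FluxRecord:
    """Despike all channels, double-rotate the wind, compute fluxes + flags."""
    channels = {}
    for name in ("u", "v", "w", "Ts", "c_co2", "c_h2o", "c_o3"):
        x = getattr(block, name)
        channels[name] = despike(x, k_mad)[0] if x is not None else None
    u, v, w, _, _ = double_rotation(channels["u"], channels["v"], channels["w"])
    clean = HighFrequencyBlock(t=block.t, u=u, v=v, w=w, Ts=channels["Ts"],
                               c_co2=channels["c_co2"], c_h2o=channels["c_h2o"],
                               c_o3=channels["c_o3"])
    rec = block_fluxes(clean, rho, cp, timestamp=timestamp,
                       literal_eq3=literal_eq3)
    rec.missing_frac = max(block.missing_fraction(c) for c in ("u", "v", "w", "Ts"))
    rec.ss_class, rec.itc_class = ssitc_flags(clean)
    return rec
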