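"""Flux-based phytotoxic ozone dose and concentration-based exposure metrics.

POD6 integrates the stomatal O3 flux above a 6 nmol m^-2 s^-1 detoxification
threshold over daytime half-hours:

    POD6 = sum_i max(0, Flux_s,i - 6) * 1800  [nmol m^-2 -> umol m^-2]

AOT40 accumulates half-hourly exceedances over 40 ppb and W126 applies the
sigmoid weight W = 1/(1 + 4403 exp(-126 [O3]/1000)) to each sample; both are
accumulated per sample without a 0.5-h weight (the half-hourly dialect), with
an hourly-mean dialect that first averages the two half-hours of each clock
hour. Daily values sum into seasonal accumulations over three day sets: all
concentration-valid days and the intersections with the days on which each
POD6 estimate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

SECONDS_PER_HALFHOUR = 1800.0
POD_THRESHOLD = 6.0     # nmol m^-2 s^-1
AOT_THRESHOLD = 40.0    # ppb
W126_M = 4403.0
W126_A = 126.0


def stomatal_o3_flux(ratio, vd, conc_nmol_m3):
    """Stomatal O3 flux (nmol m^-2 s^-1) = (Gs_O3/Gc_O3) * Vd * [O3].

    ``ratio`` outside [0, 1] yields NaN (excluded record).
    """
    ratio = np.asarray(ratio, dtype=float)
    total = np.asarray(vd, dtype=float) * np.asarray(conc_nmol_m3, dtype=float)
    ok = np.isfinite(ratio) & (ratio >= 0.0) & (ratio <= 1.0)
    return np.where(ok, ratio * total, np.nan)


def w126_weight(conc_ppb):
    """Sigmoid W126 weight, strictly increasing and bounded in (0, 1)."""
    c = np.asarray(conc_ppb, dtype=float)
    return 1.0 / (1.0 + W126_M * np.exp(-W126_A * c / 1000.0))


def pod6_daily(flux_stom):
    """Daily POD6 (umol m^-2) from daytime half-hourly stomatal flux."""
    f = np.asarray(flux_stom, dtype=float)
    f = f[np.isfinite(f)]
    return float(np.sum(np.maximum(0.0, f - POD_THRESHOLD))
                 * SECONDS_PER_HALFHOUR / 1000.0)


def aot40_daily(conc_ppb, dialect: str = "halfhourly"):
    """Daily AOT40 (ppb accumulated per sample, reported as ppb h).

    ``halfhourly`` sums per-sample exceedances with no 0.5-h weight;
    ``hourly_mean`` first averages each consecutive pair of half-hours.
    """
    c = np.asarray(conc_ppb, dtype=float)
    c = c[np.isfinite(c)]
    if dialect == "hourly_mean":
        c = _hourly_means(c)
    elif dialect != "halfhourly":
        raise ValueError(f"unknown AOT40 dialect {dialect!r}")
    return float(np.sum(np.maximum(0.0, c - AOT_THRESHOLD)))


def w126_daily(conc_ppb, dialect: str = "halfhourly"):
    """Daily W126 (ppb, per-sample accumulation matching the AOT40 dialect)."""
    c = np.asarray(conc_ppb, dtype=float)
    c = c[np.isfinite(c)]
    if dialect == "hourly_mean":
        c = _hourly_means(c)
    elif dialect != "halfhourly":
        raise ValueError(f"unknown W126 dialect {dialect!r}")
    return float(np.sum(w126_weight(c) * c))


def _hourly_means(c: np.ndarray) -> np.ndarray:
    if len(c) % 2:
        c = c[:-1]
    return c.reshape(-1, 2).mean(axis=1)


def diurnal_centroid(values, hours, window=(7.0, 17.0), min_points: int = 9):
    """Value-weighted mean hour of day over the daylight window.

    Returns NaN when fewer than ``min_points`` valid points fall in the
    window or all weights are zero. Weights must be non-negative.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(hours, dtype=float)
    sel = (t >= window[0]) & (t <= window[1]) & np.isfinite(v)
    v, t = v[sel], t[sel]
    if len(v) < min_points:
        return np.nan
    if np.any(v < 0):
        raise ValueError("centroid weights must be non-negative")
    tot = v.sum()
    if tot == 0:
        return np.nan
    return float(np.sum(v * t) / tot)


@dataclass
class DailyDose:
    """Daily dose/exposure metrics for one calendar day."""

    date: pd.Timestamp
    pod6_med: float
    pod6_pm: float
    aot40: float
    w126: float
    n_conc: int
    n_med: int
    n_pm: int
    centroids: dict = field(default_factory=dict)


def daily_metrics(df: pd.DataFrame, daytime_mask, dialect: str = "halfhourly",
                  min_samples_day: int = 5,
                  centroid_window=(7.0, 17.0),
                  min_points_centroid: int = 9) -> pd.DataFrame:
    """Per-day POD6 (both estimates), AOT40, W126 and diurnal centroids.

    ``df`` needs TIMESTAMP, O3, FLUX_STOM_MED, FLUX_STOM_PM (the latter two
    may be NaN on invalid records); only rows where ``daytime_mask`` is True
    enter any metric. POD6 for a day is emitted only when at least
    ``min_samples_day`` valid stomatal-flux half-hours exist that day; the
    same floor applies to the concentration metrics.
    """
    day = pd.DatetimeIndex(df["TIMESTAMP"]).normalize()
    hours = (pd.DatetimeIndex(df["TIMESTAMP"]).hour
             + pd.DatetimeIndex(df["TIMESTAMP"]).minute / 60.0)
    work = pd.DataFrame({
        "day": day, "hour": hours,
        "O3": df["O3"].to_numpy(dtype=float),
        "MED": df.get("FLUX_STOM_MED", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float),
        "PM": df.get("FLUX_STOM_PM", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float),
    })
    work = work[np.asarray(daytime_mask, dtype=bool)]
    rows = []
    for d, g in work.groupby("day"):
        n_conc = int(np.isfinite(g["O3"]).sum())
        n_med = int(np.isfinite(g["MED"]).sum())
        n_pm = int(np.isfinite(g["PM"]).sum())
        rows.append({
            "date": d,
            "pod6_med": pod6_daily(g["MED"]) if n_med >= min_samples_day else np.nan,
            "pod6_pm": pod6_daily(g["PM"]) if n_pm >= min_samples_day else np.nan,
            "aot40": aot40_daily(g["O3"], dialect) if n_conc >= min_samples_day else np.nan,
            "w126": w126_daily(g["O3"], dialect) if n_conc >= min_samples_day else np.nan,
            "n_conc": n_conc, "n_med": n_med, "n_pm": n_pm,
            "centroid_o3": diurnal_centroid(
                np.maximum(0, g["O3"]), g["hour"], centroid_window, min_points_centroid),
            "centroid_flux_med": diurnal_centroid(
                np.maximum(0, np.nan_to_num(g["MED"], nan=np.nan)), g["hour"],
                centroid_window, min_points_centroid),
            "centroid_flux_pm": diurnal_centroid(
                np.maximum(0, np.nan_to_num(g["PM"], nan=np.nan)), g["hour"],
                centroid_window, min_points_centroid),
        })
    return pd.DataFrame(rows)


def accumulate_metrics(daily: pd.DataFrame) -> pd.DataFrame:
    """Seasonal sums over three day-set variants.

    ``all_days`` uses every concentration-valid day; ``intersect_med`` and
    ``intersect_pm`` restrict AOT40/W126 to days where the corresponding POD6
    exists (so the exposure and dose share a day set). Sums are returned with
    the day counts they used.
    """
    if daily.empty:
        z = {"pod6_med": 0.0, "pod6_pm": 0.0, "aot40": 0.0, "w126": 0.0,
             "n_days": 0}
        return pd.DataFrame([{**z, "variant": v}
                             for v in ("all_days", "intersect_med", "intersect_pm")]
                            ).set_index("variant")
    conc_ok = daily["aot40"].notna()
    med_ok = daily["pod6_med"].notna()
    pm_ok = daily["pod6_pm"].notna()
    out = []
    for variant, sel in (("all_days", conc_ok),
                         ("intersect_med", conc_ok & med_ok),
                         ("intersect_pm", conc_ok & pm_ok)):
        g = daily[sel]
        out.append({
            "variant": variant,
            "pod6_med": float(np.nansum(g["pod6_med"])),
            "pod6_pm": float(np.nansum(g["pod6_pm"])),
            "aot40": float(g["aot40"].sum()),
            "w126": float(g["w126"].sum()),
            "n_days": int(sel.sum()),
        })
    return pd.DataFrame(out).set_index("variant")


RAIN_WINDOWS_H = (24, 36, 48, 60, 72)
RH_THRESHOLDS = (0.7, 0.8, 0.9)


def filter_grid():
    """The 15 data filters: 5 post-rain windows x 3 RH thresholds."""
    return [{"rain_window_h": rw, "rh_max": rh * 100.0}
            for rw, rh in product(RAIN_WINDOWS_H, RH_THRESHOLDS)]


def sensitivity_grid(run_filter) -> pd.DataFrame:
    """Re-run the conductance+dose stages for 15 filters x 2 parameter modes.

    ``run_filter(rain_window_h, rh_max, season_wide)`` must return the
    accumulated-metrics table from :func:`accumulate_metrics` (or None when
    the filter leaves no fittable windows). Returns one row per grid cell
    (30 for a complete run) plus min/max bounds columns computed downstream.
    """
    rows = []
    for i, filt in enumerate(filter_grid()):
        for mode in ("moving", "fixed"):
            acc = run_filter(filt["rain_window_h"], filt["rh_max"],
                             season_wide=(mode == "fixed"))
            row = {"filter_id": i, "rain_window_h": filt["rain_window_h"],
                   "rh_max": filt["rh_max"], "mode": mode,
                   "available": acc is not None}
            if acc is not None:
                for variant in ("all_days", "intersect_med", "intersect_pm"):
                    for m in ("pod6_med", "pod6_pm", "aot40", "w126", "n_days"):
                        row[f"{m}_{variant}"] = acc.loc[variant, m]
            rows.append(row)
    return pd.DataFrame(rows)


def grid_bounds(grid: pd.DataFrame) -> dict:
    """Min/max bounds per metric across available grid cells, and the mean
    moving-vs-fixed POD6 difference."""
    ok = grid[grid["available"]]
    bounds = {}
    for m in ("pod6_med_intersect_med", "pod6_pm_intersect_pm",
              "aot40_intersect_med", "w126_intersect_med",
              "aot40_intersect_pm", "w126_intersect_pm"):
        if m in ok:
            bounds[m] = (float(ok[m].min()), float(ok[m].max()))
    if {"moving", "fixed"} <= set(ok["mode"]):
        piv = ok.pivot_table(index="filter_id", columns="mode",
                             values="pod6_med_intersect_med")
        if {"moving", "fixed"} <= set(piv.columns):
            diff = piv["moving"] - piv["fixed"]
            bounds["pod6_med_moving_minus_fixed_mean"] = float(diff.mean())
    return bounds
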