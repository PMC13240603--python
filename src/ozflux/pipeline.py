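"""End-to-end staging: simulate -> partition -> deposition -> conductance -> dose.

`analyze` runs the half-hourly analysis in memory and returns every stage
product; `run_pipeline` wraps it with file I/O, resolved-config and
provenance output for the CLI.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import conductance as cond
from . import deposition as depo
from . import dose
from . import meteo
from . import partition as cpart
from .io import RunConfig, SiteMeta, write_halfhourly
from .solar import solar_position
from .synthetic import TruthParams, gen_halfhourly_truth, gen_meteorology

log = logging.getLogger("ozflux")


def analyze(obs: pd.DataFrame, site: SiteMeta, config: RunConfig | None = None,
            rain_window_h: float | None = None, rh_max: float | None = None,
            season_wide: bool = False, with_grid: bool = False) -> dict:
    """Run partition -> deposition -> conductance -> dose on a half-hourly table.

    ``rain_window_h`` / ``rh_max`` override the config filter (used by the
    sensitivity grid). Returns a dict of stage outputs and bookkeeping.
    """
    config = config or RunConfig(site=site)
    rain_window_h = config.rain_window_h if rain_window_h is None else rain_window_h
    rh_max = config.rh_max if rh_max is None else rh_max

    df = obs.copy()
    times = pd.DatetimeIndex(df["TIMESTAMP"])
    pos = solar_position(times, site.latitude, site.longitude, site.utc_offset)
    night = pos["elevation"].to_numpy() <= 0.0
    df["NEE"] = df["FC"]

    # u* screening of nighttime NEE via monthly change points (19:00-03:00)
    cp_mask = cpart.changepoint_hours_mask(times)
    sel = cp_mask & np.isfinite(df["NEE"]) & np.isfinite(df["USTAR"])
    ustar_result = None
    n_night_removed = 0
    if sel.sum() >= 30:
        try:
            ustar_result = cpart.ustar_changepoint(
                df.loc[sel, "NEE"], df.loc[sel, "USTAR"],
                times[sel].month)
        except ValueError:
            ustar_result = None
    if ustar_result is not None and not ustar_result.unreliable:
        low = night & (df["USTAR"].to_numpy() < ustar_result.threshold)
        n_night_removed = int((low & np.isfinite(df["NEE"])).sum())
        df.loc[low, "NEE"] = np.nan

    # gap-fill NEE for partitioning
    drivers = pd.DataFrame({
        "TIMESTAMP": times, "SW_IN": df["SW_IN"], "TA": df["TA"],
        "VPD": meteo.vpd(df["TA"], df["RH"]),
    })
    filled, fill_flags = cpart.gapfill_lut(df["NEE"].to_numpy(), drivers)
    df["NEE"] = filled
    df["FILL_FLAG"] = fill_flags

    part = cpart.partition_nee(df, night)
    df = part.table

    df = depo.add_deposition_columns(df, site.measurement_height,
                                     site.canopy_height)
    df, fits, excl = cond.add_conductance_columns(
        df, site.latitude, site.longitude, site.utc_offset,
        rain_window_h=rain_window_h, rh_max=rh_max, sza_max=config.sza_max,
        ca_umol=config.ca_umol, sqrt_vpd=config.medlyn_sqrt_vpd,
        season_wide=season_wide)

    conc = df["O3_NMOL_M3"].to_numpy()
    for which in ("MED", "PM"):
        ratio = df[f"RATIO_{which}"].to_numpy()
        ratio = np.where(df[f"VALID_{which}"], ratio, np.nan)
        df[f"FLUX_STOM_{which}"] = dose.stomatal_o3_flux(
            ratio, df["VD_O3"].to_numpy(), conc)
        df[f"FRAC_{which}"] = np.where(np.isfinite(df[f"FLUX_STOM_{which}"]),
                                       ratio, np.nan)

    daytime = pos["zenith"].to_numpy() < 90.0
    daily = dose.daily_metrics(
        df, daytime, dialect=config.aot40_dialect,
        min_samples_day=config.min_samples_day,
        centroid_window=config.daylight_window,
        min_points_centroid=config.min_points_centroid)
    seasonal = dose.accumulate_metrics(daily)

    result = {
        "table": df, "daily": daily, "seasonal": seasonal, "fits": fits,
        "ustar": ustar_result, "n_night_removed": n_night_removed,
        "e0": part.e0, "window_rref": part.window_rref,
        "n_gpp_clipped": part.n_gpp_clipped, "exclusions": excl,
        "night": night, "daytime": daytime,
    }
    if with_grid:
        result["grid"] = run_sensitivity_grid(obs, site, config)
    return result


def run_sensitivity_grid(obs: pd.DataFrame, site: SiteMeta,
                         config: RunConfig) -> pd.DataFrame:
    """15 filters x {moving, fixed} Medlyn parameter modes."""

    def run_filter(rain_window_h, rh_max, season_wide):
        try:
            res = analyze(obs, site, config, rain_window_h=rain_window_h,
                          rh_max=rh_max, season_wide=season_wide)
        except ValueError:
            return None
        if not res["fits"]:
            return None
        return res["seasonal"]

    return dose.sensitivity_grid(run_filter)


def simulate(config: RunConfig):
    """Generate a synthetic season per the config's truth block."""
    params = TruthParams(**config.truth) if config.truth else TruthParams(seed=config.seed)
    met = gen_meteorology(config.days, params, config.site)
    return gen_halfhourly_truth(met, params, config.site)


def run_pipeline(config: RunConfig, with_grid: bool = False) -> Path:
    """Execute the pipeline and write stage outputs to the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "stage_version": "ozflux-0.1"}

    if config.obs_file:
        from .io import read_halfhourly
        obs = read_halfhourly(config.obs_file)
    else:
        obs, truth = simulate(config)
        write_halfhourly(obs, out / "observations.csv", prov)
        write_halfhourly(truth, out / "truth_sidecar.csv", prov)

    site = config.site
    res = analyze(obs, site, config, with_grid=with_grid)
    write_halfhourly(res["table"], out / "halfhourly_products.csv", prov)
    res["daily"].to_csv(out / "daily_metrics.csv", index=False)
    res["seasonal"].to_csv(out / "seasonal_accumulation.csv")
    if with_grid:
        res["grid"].to_csv(out / "sensitivity_grid.csv", index=False)

    summary = {
        "config_hash": config.config_hash(),
        "n_records": int(len(res["table"])),
        "ustar_threshold": (None if res["ustar"] is None
                            else res["ustar"].threshold),
        "n_night_removed": res["n_night_removed"],
        "e0": res["e0"],
        "n_medlyn_fits": len(res["fits"]),
        "exclusions": {k: int(v) for k, v in res["exclusions"].items()},
        "seasonal": json.loads(res["seasonal"].to_json()),
    }
    if with_grid:
        summary["grid_bounds"] = dose.grid_bounds(res["grid"])
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    config.write_resolved(out / "resolved_config.yaml")
    return out
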