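"""Readers, writers and run configuration.

The canonical on-disk dialect is AmeriFlux-style delimited text: comma
separated, TIMESTAMP_START/TIMESTAMP_END as YYYYMMDDHHMM in local standard
time (end-of-interval labelled), -9999 for missing. Provenance lines
starting with '#' may precede the header and are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MISSING = -9999.0

MANDATORY_COLUMNS = ("TIMESTAMP_START", "TIMESTAMP_END")


@dataclass
class SiteMeta:
    """Tower site metadata."""

    latitude: float = 40.0062
    longitude: float = -88.2904
    measurement_height: float = 3.5     # m
    canopy_height: float = 2.05         # m (peak)
    utc_offset: float = -6.0            # h, local standard time
    lai: float = 4.0                    # m^2 m^-2 (peak-season)

    def __post_init__(self) -> None:
        if self.measurement_height <= self.canopy_height:
            raise ValueError("measurement height must exceed canopy height")
        if self.lai < 0:
            raise ValueError("LAI must be non-negative")

    @property
    def displacement_height(self) -> float:
        return 0.67 * self.canopy_height


def read_halfhourly(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an AmeriFlux-style half-hourly table.

    Applies the -9999 sentinel, parses timestamps, checks monotonicity and
    adds a TIMESTAMP convenience column (end of interval). ``column_map``
    renames caller columns onto the canonical names.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col}")
    df = df.replace(MISSING, np.nan)
    ts = pd.to_datetime(df["TIMESTAMP_END"].astype("int64").astype(str),
                        format="%Y%m%d%H%M")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    df["TIMESTAMP"] = ts
    return df


def write_halfhourly(df: pd.DataFrame, path, provenance: dict | None = None):
    """Write a half-hourly table, NaN -> -9999, optional provenance header."""
    path = Path(path)
    out = df.copy()
    if "TIMESTAMP" in out.columns:
        out = out.drop(columns=["TIMESTAMP"])
    out = out.fillna(MISSING)
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        out.to_csv(fh, index=False)


def write_highfreq_block(block, path) -> None:
    """Write one 10 Hz block as delimited text (one file per half-hour)."""
    cols = {"t": block.t, "u": block.u, "v": block.v, "w": block.w,
            "Ts": block.Ts}
    for name in ("c_co2", "c_h2o", "c_o3"):
        x = getattr(block, name)
        if x is not None:
            cols[name] = x
    pd.DataFrame(cols).to_csv(path, index=False)


def read_highfreq_block(path):
    """Read a 10 Hz block written by :func:`write_highfreq_block`."""
    from .ecflux import HighFrequencyBlock
    df = pd.read_csv(path)
    kw = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    return HighFrequencyBlock(**kw)


def daily_lai(samples) -> float:
    """Site LAI for one date: mean after dropping robust outliers.

    A sample is an outlier when it lies more than 1.5 IQR from the median
    (the median-centred fence behaves sensibly for the handful of samples a
    survey day yields, where interpolated quartile fences collapse).
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("need at least one LAI sample")
    if len(x) < 3:
        return float(np.mean(x))
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    med = np.median(x)
    keep = np.abs(x - med) <= 1.5 * iqr
    return float(np.mean(x[keep]))


_KNOWN_KEYS = {
    "site", "days", "seed", "out_dir", "raw_dir", "obs_file",
    "rain_window_h", "rh_max", "sza_max", "daylight_window",
    "min_points_centroid", "min_samples_day", "ca_umol",
    "medlyn_sqrt_vpd", "dt_weight", "wpl_correction", "literal_eq3",
    "aot40_dialect", "truth",
}


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    site: SiteMeta = field(default_factory=SiteMeta)
    days: int = 62
    seed: int = 0
    out_dir: str = "ozflux_out"
    obs_file: str | None = None
    rain_window_h: float = 36.0
    rh_max: float = 80.0
    sza_max: float = 85.0
    daylight_window: tuple = (7.0, 17.0)
    min_points_centroid: int = 9
    min_samples_day: int = 5
    ca_umol: float = 420.0
    medlyn_sqrt_vpd: bool = False
    dt_weight: bool = False
    wpl_correction: bool = False
    literal_eq3: bool = False
    aot40_dialect: str = "halfhourly"
    truth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        site = SiteMeta(**raw.pop("site", {}))
        if "daylight_window" in raw:
            raw["daylight_window"] = tuple(raw["daylight_window"])
        return cls(site=site, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["daylight_window"] = list(self.daylight_window)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("obs_file", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
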