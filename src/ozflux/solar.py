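"""NOAA-style solar geometry: zenith angle and elevation for tower timestamps.

Timestamps are local standard time (no DST); the site's UTC offset converts
to true solar time through the equation of time and the site longitude.
Accuracy (~0.1 deg zenith) is ample for daylight masks and SZA filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_position(times: pd.DatetimeIndex, lat_deg: float, lon_deg: float,
                   utc_offset_h: float) -> pd.DataFrame:
    """Solar zenith and elevation angles (degrees) for local-standard times.

    Returns a DataFrame indexed like ``times`` with columns
    ``zenith``, ``elevation`` and ``declination``.
    """
    times = pd.DatetimeIndex(times)
    doy = times.dayofyear.to_numpy(dtype=float)
    frac_hour = (times.hour + times.minute / 60.0
                 + times.second / 3600.0).to_numpy(dtype=float)

    # fractional year, radians
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (frac_hour - 12.0) / 24.0)

    # equation of time, minutes (NOAA Fourier fit)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma)
                       - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma)
                       - 0.040849 * np.sin(2 * gamma))
    # solar declination, radians
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))

    time_offset = eqtime + 4.0 * lon_deg - 60.0 * utc_offset_h
    tst = frac_hour * 60.0 + time_offset          # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)            # hour angle, radians

    lat = np.deg2rad(lat_deg)
    cos_zen = (np.sin(lat) * np.sin(decl)
               + np.cos(lat) * np.cos(decl) * np.cos(ha))
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    zen = np.rad2deg(np.arccos(cos_zen))
    return pd.DataFrame(
        {"zenith": zen, "elevation": 90.0 - zen, "declination": np.rad2deg(decl)},
        index=times,
    )


def solar_elevation(times, lat_deg, lon_deg, utc_offset_h):
    """Solar elevation angle in degrees (convenience wrapper)."""
    return solar_position(times, lat_deg, lon_deg, utc_offset_h)["elevation"].to_numpy()
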