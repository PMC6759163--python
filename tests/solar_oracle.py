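"""Independent solar-position oracle for the test suite.

A from-scratch transcription of the NOAA solar calculator spreadsheet
(General Solar Position Calculations, NOAA Global Monitoring Division),
kept deliberately separate from the package implementation: computations
proceed cell-by-cell as in the spreadsheet, in degrees, using the Julian
day / Julian century chain.  Accuracy is a few hundredths of a degree over
1900-2100, ample for checking civil-twilight crossing times to the minute.
"""

from __future__ import annotations

import math

import pandas as pd

D2R = math.pi / 180.0
R2D = 180.0 / math.pi


def solar_elevation_noaa(when, lat: float, lon: float) -> float:
    """Geometric solar elevation (degrees), no refraction."""
    ts = pd.Timestamp(when)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    ts = ts.tz_convert("UTC")

    jd = ts.value / 1e9 / 86400.0 + 2440587.5
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    eq_of_center = (
        math.sin(geom_mean_anom * D2R)
        * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * geom_mean_anom * D2R) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * geom_mean_anom * D2R) * 0.000289
    )
    true_long = geom_mean_long + eq_of_center
    app_long = true_long - 0.00569 - 0.00478 * math.sin((125.04 - 1934.136 * jc) * D2R)

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos((125.04 - 1934.136 * jc) * D2R)

    declination = R2D * math.asin(
        math.sin(obliq_corr * D2R) * math.sin(app_long * D2R)
    )

    var_y = math.tan(obliq_corr / 2.0 * D2R) ** 2
    eq_time = 4.0 * R2D * (
        var_y * math.sin(2.0 * geom_mean_long * D2R)
        - 2.0 * ecc * math.sin(geom_mean_anom * D2R)
        + 4.0 * ecc * var_y * math.sin(geom_mean_anom * D2R) * math.cos(2.0 * geom_mean_long * D2R)
        - 0.5 * var_y * var_y * math.sin(4.0 * geom_mean_long * D2R)
        - 1.25 * ecc * ecc * math.sin(2.0 * geom_mean_anom * D2R)
    )

    minutes_past_midnight = (
        ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7
    )
    true_solar_min = (minutes_past_midnight + eq_time + 4.0 * lon) % 1440.0
    hour_angle = true_solar_min / 4.0 - 180.0
    if hour_angle < -180.0:
        hour_angle += 360.0

    cos_zenith = (
        math.sin(lat * D2R) * math.sin(declination * D2R)
        + math.cos(lat * D2R) * math.cos(declination * D2R) * math.cos(hour_angle * D2R)
    )
    cos_zenith = max(-1.0, min(1.0, cos_zenith))
    return 90.0 - R2D * math.acos(cos_zenith)
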