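"""Sunrise and sunset times from the NOAA solar-position equations.

GPS fixes are scheduled on a regular grid between local sunrise and sunset,
so both the synthetic generator and the preprocessing module need civil
sunrise/sunset for an arbitrary date and location.  This implements the
low-order NOAA approximation (fractional-year Fourier series for the
equation of time and solar declination, zenith 90.833 deg); accuracy is a
couple of minutes, well below the 5-min fix interval.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = ["sun_times", "PolarDayError"]


class PolarDayError(ValueError):
    """The sun does not rise (or does not set) on this date/latitude."""


def _gamma(doy: int, hour: float) -> float:
    return 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)

def _eqtime_min(g: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )

def _decl_rad(g: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def sun_times(date: dt.date, lat: float, lon: float) -> tuple[dt.datetime, dt.datetime]:
    """Civil sunrise and sunset as UTC datetimes.

    Parameters
    ----------
    date : datetime.date
    lat, lon : float
        Degrees; longitude positive east.

    Raises
    ------
    PolarDayError
        If the sun never crosses the horizon on that date (polar day/night).
    """
    doy = date.timetuple().tm_yday
    g = _gamma(doy, 12.0)
    decl = _decl_rad(g)
    lat_r = math.radians(lat)
    zenith = math.radians(90.833)
    cos_ha = (math.cos(zenith) - math.sin(lat_r) * math.sin(decl)) / (
        math.cos(lat_r) * math.cos(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise PolarDayError(
            f"no sunrise/sunset at latitude {lat} on {date.isoformat()}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    eqtime = _eqtime_min(g)
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    midnight = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return (
        midnight + dt.timedelta(minutes=sunrise_min),
        midnight + dt.timedelta(minutes=sunset_min),
    )
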