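"""Sunrise/sunset times from the NOAA solar-position equations.

Accuracy is about a minute at mid-latitudes, ample for anchoring diel
activity times to the solar day.
"""

from __future__ import annotations

import numpy as np

_ZENITH_OFFICIAL = np.deg2rad(90.833)  # refraction + solar disc radius


def _solar_geometry(day_of_year: np.ndarray):
    g = 2.0 * np.pi / 365.0 * (day_of_year - 1 + 0.5)  # fractional year at solar noon
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                       - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    return eqtime, decl


def sun_events_utc(day_of_year: np.ndarray, lat: float, lon: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sunrise and sunset in UTC hours for given days of year.

    Raises for polar day/night (no sunrise at that latitude and date).
    """
    doy = np.atleast_1d(np.asarray(day_of_year, dtype=float))
    eqtime, decl = _solar_geometry(doy)
    phi = np.deg2rad(lat)
    cos_ha = (np.cos(_ZENITH_OFFICIAL) / (np.cos(phi) * np.cos(decl))
              - np.tan(phi) * np.tan(decl))
    if np.any(np.abs(cos_ha) > 1):
        raise ValueError("no sunrise/sunset at this latitude and date (polar day/night)")
    ha = np.rad2deg(np.arccos(cos_ha))
    sunrise = (720.0 - 4.0 * (lon + ha) - eqtime) / 60.0
    sunset = (720.0 - 4.0 * (lon - ha) - eqtime) / 60.0
    return sunrise, sunset
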