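"""Independent solar-position oracle: Michalsky (1988) approximate ephemeris.

Implemented separately from the package (different published algorithm,
different formulation) so solar-position tests compare two independent
routes.  No refraction correction, matching the package's convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def michalsky_solar_position(timestamp_utc, latitude: float, longitude: float):
    """Return (azimuth, elevation) in degrees; azimuth 0 = north, clockwise."""
    t = pd.Timestamp(timestamp_utc)
    jd = t.to_julian_date()
    time = jd - 2451545.0

    mnlong = (280.460 + 0.9856474 * time) % 360.0
    mnanom = np.deg2rad((357.528 + 0.9856003 * time) % 360.0)
    eclong = np.deg2rad(
        (mnlong + 1.915 * np.sin(mnanom) + 0.020 * np.sin(2.0 * mnanom)) % 360.0
    )
    oblqec = np.deg2rad(23.439 - 0.0000004 * time)

    ra = np.arctan2(np.cos(oblqec) * np.sin(eclong), np.cos(eclong)) % (2.0 * np.pi)
    dec = np.arcsin(np.sin(oblqec) * np.sin(eclong))

    hour_ut = t.hour + t.minute / 60.0 + t.second / 3600.0
    gmst = (6.697375 + 0.0657098242 * time + hour_ut) % 24.0
    lmst = (gmst + longitude / 15.0) % 24.0
    ha = np.deg2rad(((lmst * 15.0 - np.rad2deg(ra)) + 180.0) % 360.0 - 180.0)

    lat = np.deg2rad(latitude)
    el = np.arcsin(
        np.sin(dec) * np.sin(lat) + np.cos(dec) * np.cos(lat) * np.cos(ha)
    )
    az = np.arctan2(
        -np.cos(dec) * np.sin(ha),
        np.sin(dec) * np.cos(lat) - np.cos(dec) * np.sin(lat) * np.cos(ha),
    )
    return float(np.rad2deg(az) % 360.0), float(np.rad2deg(el))
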