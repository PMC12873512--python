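"""Solar geometry and effective irradiance on tilted canopy surfaces.

Horizontally mounted quantum sensors under-report the photon flux carried by
the direct solar beam by a factor of ``sin(elevation)``.  For canopy surfaces
on steep alpine slopes the quantity of interest is instead the beam flux
projected onto the canopy surface normal.  This module computes solar
position, converts a horizontal PPFD record to an estimate of the beam value
(the *corrected* PPFD), and projects that onto an arbitrarily oriented
surface via the scalar product of the sun direction and the surface normal
(the *effective* PPFD).

Solar position follows the NOAA "General Solar Position Calculations"
equations (fractional-year Fourier series for declination and the equation
of time), which are accurate to well under 0.5 degrees over the years of
interest — sufficient for irradiance projection.

Conventions
-----------
* Azimuth: degrees clockwise from geographic north, in ``[0, 360)``.
* Elevation: degrees above the horizon, in ``[-90, 90]``.
* The sine correction is only applied for solar elevations above 10 degrees;
  below that, measured flux is dominated by diffuse light and the 1/sin
  factor would blow up, so the measured value is passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "SolarPosition",
    "SurfaceNormal",
    "EffectivePpfdSeries",
    "solar_position",
    "correct_ppfd",
    "direction_vector",
    "effective_ppfd",
    "effective_ppfd_series",
    "daily_maxima",
    "PPFD_CORRECTION_CUTOFF_DEG",
]

#: Solar elevation (degrees) below which no 1/sin correction is applied.
PPFD_CORRECTION_CUTOFF_DEG = 10.0


@dataclass(frozen=True)
class SolarPosition:
    """Topocentric solar position (degrees)."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.elevation <= 90.0):
            raise ValueError(f"elevation out of range: {self.elevation}")
        if not (0.0 <= self.azimuth < 360.0):
            raise ValueError(f"azimuth out of range: {self.azimuth}")


@dataclass(frozen=True)
class SurfaceNormal:
    """Orientation of a canopy surface, given by its normal vector.

    ``elevation`` is the angle of the normal above the horizontal plane
    (90 degrees for a flat, horizontal surface); ``azimuth`` is the compass
    direction the surface faces.  A slope inclined by ``i`` degrees has a
    normal elevation of ``90 - i``.
    """

    elevation: float
    azimuth: float

    def __post_init__(self) -> None:
        if not (0.0 < self.elevation <= 90.0):
            raise ValueError(f"normal elevation must be in (0, 90]: {self.elevation}")


@dataclass
class EffectivePpfdSeries:
    """Per-timestamp measured, beam-corrected and surface-projected PPFD."""

    timestamps: pd.DatetimeIndex
    ppfd_measured: np.ndarray
    ppfd_corrected: np.ndarray
    ppfd_effective: np.ndarray
    solar_elevation: np.ndarray
    solar_azimuth: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ppfd_measured": self.ppfd_measured,
                "ppfd_corrected": self.ppfd_corrected,
                "ppfd_effective": self.ppfd_effective,
                "solar_elevation": self.solar_elevation,
                "solar_azimuth": self.solar_azimuth,
            },
            index=self.timestamps,
        )


# ---------------------------------------------------------------------------
# Solar position (NOAA general solar position calculations)
# ---------------------------------------------------------------------------

def _fractional_year(ts: pd.DatetimeIndex) -> np.ndarray:
    """Fractional year gamma in radians (leap-year aware)."""
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0 + ts.second.to_numpy() / 3600.0
    days_in_year = np.where(ts.is_leap_year, 366.0, 365.0)
    return 2.0 * np.pi / days_in_year * (doy - 1.0 + (hour - 12.0) / 24.0)


def _solar_position_arrays(
    ts: pd.DatetimeIndex, latitude: float, longitude: float
) -> tuple[np.ndarray, np.ndarray]:
    g = _fractional_year(ts)
    # Equation of time [minutes] and solar declination [radians].
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    minutes_utc = (
        ts.hour.to_numpy() * 60.0 + ts.minute.to_numpy() + ts.second.to_numpy() / 60.0
    )
    true_solar_time = minutes_utc + eqtime + 4.0 * longitude  # minutes
    hour_angle = np.deg2rad(true_solar_time / 4.0 - 180.0)
    lat = np.deg2rad(latitude)

    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    sin_elev = np.clip(sin_elev, -1.0, 1.0)
    elevation = np.rad2deg(np.arcsin(sin_elev))

    cos_elev = np.cos(np.arcsin(sin_elev))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = (np.sin(decl) - np.sin(lat) * sin_elev) / (np.cos(lat) * cos_elev)
    cos_az = np.clip(np.nan_to_num(cos_az, nan=1.0), -1.0, 1.0)
    azimuth = np.rad2deg(np.arccos(cos_az))
    # arccos gives [0, 180]; afternoon sun (positive hour angle) is west of north.
    azimuth = np.where(np.sin(hour_angle) > 0, 360.0 - azimuth, azimuth) % 360.0
    return azimuth, elevation


def solar_position(
    timestamp_utc: datetime | str | pd.Timestamp, latitude: float, longitude: float
) -> SolarPosition:
    """Solar azimuth/elevation for a UTC timestamp at a geographic location.

    Parameters
    ----------
    timestamp_utc : datetime-like
        Moment of observation, interpreted as UTC (tz-aware input is
        converted).
    latitude, longitude : float
        Degrees; longitude positive east.
    """
    if abs(latitude) > 90.0:
        raise ValueError(f"invalid latitude: {latitude}")
    if abs(longitude) > 180.0:
        raise ValueError(f"invalid longitude: {longitude}")
    t = pd.Timestamp(timestamp_utc)
    if t.tzinfo is not None:
        t = t.tz_convert(timezone.utc).tz_localize(None)
    idx = pd.DatetimeIndex([t])
    az, el = _solar_position_arrays(idx, latitude, longitude)
    return SolarPosition(azimuth=float(az[0]), elevation=float(el[0]))


def solar_positions(
    timestamps: pd.DatetimeIndex, latitude: float, longitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`solar_position`; returns (azimuth, elevation) arrays."""
    if abs(latitude) > 90.0:
        raise ValueError(f"invalid latitude: {latitude}")
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is not None:
        ts = ts.tz_convert(timezone.utc).tz_localize(None)
    return _solar_position_arrays(ts, latitude, longitude)


# ---------------------------------------------------------------------------
# PPFD correction and projection
# ---------------------------------------------------------------------------

def correct_ppfd(ppfd_measured, elevation):
    """Convert horizontally measured PPFD to an estimate of the beam value.

    For solar elevations above 10 degrees the measured flux is divided by
    ``sin(elevation)``; at or below 10 degrees the measurement is returned
    unchanged (diffuse-dominated, correction unstable).  The rule is a step,
    deliberately discontinuous at the cutoff.
    """
    ppfd = np.asarray(ppfd_measured, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError("measured PPFD must be non-negative")
    elev = np.asarray(elevation, dtype=float)
    out = np.where(
        elev > PPFD_CORRECTION_CUTOFF_DEG,
        ppfd / np.sin(np.deg2rad(np.where(elev > PPFD_CORRECTION_CUTOFF_DEG, elev, 90.0))),
        ppfd,
    )
    if out.ndim == 0:
        return float(out)
    return out


def direction_vector(azimuth, elevation) -> np.ndarray:
    """Unit vector for a direction given as (azimuth, elevation) in degrees.

    Components are (east, north, up): ``(cos e sin a, cos e cos a, sin e)``.
    """
    a = np.deg2rad(np.asarray(azimuth, dtype=float))
    e = np.deg2rad(np.asarray(elevation, dtype=float))
    return np.stack(
        [np.cos(e) * np.sin(a), np.cos(e) * np.cos(a), np.sin(e)], axis=-1
    )


def effective_ppfd(ppfd_corrected, sun: SolarPosition, normal: SurfaceNormal):
    """Project beam PPFD onto a tilted surface.

    Returns ``ppfd_corrected * max(0, n . s)`` where ``s`` is the unit sun
    direction and ``n`` the unit surface normal; zero when the sun is at or
    below the horizon.  Negative scalar products (sun behind the surface) are
    clamped to zero.
    """
    ppfd = np.asarray(ppfd_corrected, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError("corrected PPFD must be non-negative")
    s = direction_vector(sun.azimuth, sun.elevation)
    n = direction_vector(normal.azimuth, normal.elevation)
    dot = float(np.dot(s, n))
    if sun.elevation <= 0.0:
        return 0.0 if ppfd.ndim == 0 else np.zeros_like(ppfd)
    out = ppfd * max(0.0, dot)
    return float(out) if out.ndim == 0 else out


def effective_ppfd_series(
    timestamps: pd.DatetimeIndex,
    ppfd_measured: np.ndarray,
    latitude: float,
    longitude: float,
    normal: SurfaceNormal,
    utc_offset_hours: float = 0.0,
) -> EffectivePpfdSeries:
    """Full per-minute chain: solar position, sine correction, projection.

    ``timestamps`` are site-local civil time; ``utc_offset_hours`` shifts them
    to UTC for the ephemeris.
    """
    ts = pd.DatetimeIndex(timestamps)
    ts_utc = ts - pd.Timedelta(hours=utc_offset_hours)
    az, el = solar_positions(ts_utc, latitude, longitude)
    measured = np.asarray(ppfd_measured, dtype=float)
    corrected = correct_ppfd(measured, el)
    n = direction_vector(normal.azimuth, normal.elevation)
    s = direction_vector(az, el)  # (n_t, 3)
    dot = np.clip(s @ n, 0.0, None)
    eff = np.where(el > 0.0, corrected * dot, 0.0)
    return EffectivePpfdSeries(
        timestamps=ts,
        ppfd_measured=measured,
        ppfd_corrected=corrected,
        ppfd_effective=eff,
        solar_elevation=el,
        solar_azimuth=az,
    )


def daily_maxima(series: pd.Series | pd.DataFrame, channel: str | None = None) -> pd.Series:
    """Per-calendar-day maxima of a time-indexed channel (site-local days)."""
    if isinstance(series, pd.DataFrame):
        if channel is None:
            raise ValueError("channel required for DataFrame input")
        series = series[channel]
    if len(series) == 0:
        raise ValueError("empty series")
    if not series.index.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted")
    return series.groupby(series.index.normalize()).max()
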