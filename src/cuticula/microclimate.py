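"""Summaries of 1-min canopy microclimate records.

Descriptors computed per site: pooled mean and SD of leaf temperature over
all sensors and timestamps, absolute extremes, frost-night counts (calendar
days whose minimum leaf temperature falls below a threshold), wind
statistics, and heat episodes (maximal contiguous runs during which any
sensor exceeds a threshold).  Missing samples are skipped, not interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MicroclimateSeries",
    "HeatEpisode",
    "SiteSummary",
    "summarize_site",
    "count_frost_nights",
    "detect_heat_episodes",
]


@dataclass
class MicroclimateSeries:
    """Regular site time series of leaf temperature, wind and horizontal PPFD.

    ``leaf_temperatures`` is (n_timestamps, n_sensors); timestamps are
    site-local civil time.
    """

    timestamps: pd.DatetimeIndex
    leaf_temperatures: np.ndarray  # degC, 2-D (time, sensor)
    wind_speed: np.ndarray  # m s^-1
    ppfd_horizontal: np.ndarray  # umol m^-2 s^-1
    site_name: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    normal_elevation: float = float("nan")
    normal_azimuth: float = float("nan")
    utc_offset_hours: float = 0.0
    #: optional generator ground truth: beam-normal PPFD before projection
    beam_ppfd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.leaf_temperatures = np.atleast_2d(
            np.asarray(self.leaf_temperatures, dtype=float)
        )
        if self.leaf_temperatures.shape[0] != len(self.timestamps):
            self.leaf_temperatures = self.leaf_temperatures.T
        self.wind_speed = np.asarray(self.wind_speed, dtype=float)
        self.ppfd_horizontal = np.asarray(self.ppfd_horizontal, dtype=float)
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.wind_speed[np.isfinite(self.wind_speed)] < 0):
            raise ValueError("wind speed must be non-negative")
        if np.any(self.ppfd_horizontal[np.isfinite(self.ppfd_horizontal)] < 0):
            raise ValueError("PPFD must be non-negative")

    @property
    def step_minutes(self) -> float:
        return float(np.median(np.diff(self.timestamps.asi8)) / 60e9)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"leaf_temp_{i + 1}": self.leaf_temperatures[:, i]
            for i in range(self.leaf_temperatures.shape[1])
        }
        cols["wind_speed"] = self.wind_speed
        cols["ppfd_horizontal"] = self.ppfd_horizontal
        return pd.DataFrame(cols, index=self.timestamps)


@dataclass
class HeatEpisode:
    start: pd.Timestamp
    duration_hours: float


@dataclass
class SiteSummary:
    site_name: str
    mean_leaf_temp: float
    sd_leaf_temp: float
    absolute_max_leaf_temp: float
    absolute_min_leaf_temp: float
    frost_nights: int
    mean_wind: float
    mean_daily_max_wind: float
    absolute_max_wind: float
    heat_episodes: list[HeatEpisode] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "site_name": self.site_name,
            "mean_leaf_temp": self.mean_leaf_temp,
            "sd_leaf_temp": self.sd_leaf_temp,
            "absolute_max_leaf_temp": self.absolute_max_leaf_temp,
            "absolute_min_leaf_temp": self.absolute_min_leaf_temp,
            "frost_nights": self.frost_nights,
            "mean_wind": self.mean_wind,
            "mean_daily_max_wind": self.mean_daily_max_wind,
            "absolute_max_wind": self.absolute_max_wind,
            "heat_episodes": [
                {"start": str(e.start), "duration_hours": e.duration_hours}
                for e in self.heat_episodes
            ],
        }


def count_frost_nights(series: MicroclimateSeries, threshold: float = 0.0) -> int:
    """Number of calendar days whose minimum leaf temperature is below threshold.

    The per-day minimum is taken over all sensors; days are site-local.
    """
    if len(series.timestamps) == 0:
        raise ValueError("empty series")
    per_sample_min = np.nanmin(series.leaf_temperatures, axis=1)
    daily_min = pd.Series(per_sample_min, index=series.timestamps).groupby(
        series.timestamps.normalize()
    ).min()
    return int((daily_min < threshold).sum())


def detect_heat_episodes(
    series: MicroclimateSeries, threshold: float = 40.0
) -> list[HeatEpisode]:
    """Maximal contiguous runs where any sensor exceeds the threshold.

    Episode duration is the run length times the sampling step.
    """
    hot = np.nanmax(series.leaf_temperatures, axis=1) > threshold
    step_h = series.step_minutes / 60.0
    episodes: list[HeatEpisode] = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j < n and hot[j]:
                j += 1
            episodes.append(
                HeatEpisode(start=series.timestamps[i], duration_hours=(j - i) * step_h)
            )
            i = j
        else:
            i += 1
    return episodes


def summarize_site(
    series: MicroclimateSeries,
    frost_threshold: float = 0.0,
    heat_threshold: float = 40.0,
) -> SiteSummary:
    """Pooled leaf-temperature, wind and episode descriptors for one site."""
    temps = series.leaf_temperatures
    if len(series.timestamps) == 0 or not np.isfinite(temps).any():
        raise ValueError("series has no usable leaf-temperature samples")
    finite = temps[np.isfinite(temps)]
    wind = series.wind_speed[np.isfinite(series.wind_speed)]
    daily_max_wind = (
        pd.Series(series.wind_speed, index=series.timestamps)
        .groupby(series.timestamps.normalize())
        .max()
    )
    return SiteSummary(
        site_name=series.site_name,
        mean_leaf_temp=float(finite.mean()),
        sd_leaf_temp=float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        absolute_max_leaf_temp=float(finite.max()),
        absolute_min_leaf_temp=float(finite.min()),
        frost_nights=count_frost_nights(series, frost_threshold),
        mean_wind=float(wind.mean()) if wind.size else float("nan"),
        mean_daily_max_wind=float(daily_max_wind.mean()),
        absolute_max_wind=float(wind.max()) if wind.size else float("nan"),
        heat_episodes=detect_heat_episodes(series, heat_threshold),
    )
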