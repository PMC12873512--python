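"""Synthetic study inputs with known ground truth.

Every downstream stage of the pipeline can be exercised without field data:
this module generates (a) diurnal alpine microclimate series with
controllable frost/heat/cloud structure, (b) bench-drying mass-loss records
from a forward conductance model with known true g_min, (c) layered cuticle
Raman cubes built from Gaussian-band endmember spectra with baseline, noise
and cosmic-ray artefacts, and (d) normally distributed cuticle-thickness
groups.

The default site scenarios are calibrated to a field study of an alpine
dwarf shrub on two contrasting slopes (north-facing vs southeast-facing at
~2237 m): canopy-normal geometry 45 deg/350 deg (N) and 35 deg/135 deg (SE),
mean leaf temperatures 10.3 / 13.8 degC, g_min group means per exposure
temperature, and site/side cuticle-thickness means.  Those calibrations are
the ground truth that recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .conductance import (
    MOLAR_MASS_WATER,
    DryingExperiment,
    vpd_mole_fraction,
)
from .microclimate import MicroclimateSeries
from .raman import RamanCube
from .solar import solar_positions
from .stats import ThicknessDataset

__all__ = [
    "SiteScenario",
    "DryingForwardParams",
    "N_SITE",
    "S_SITE",
    "GMIN_CALIBRATION_N",
    "GMIN_CALIBRATION_S",
    "THICKNESS_SIDE_N",
    "THICKNESS_SIDE_S",
    "THICKNESS_SITE",
    "ENDMEMBER_BANDS",
    "endmember_spectrum",
    "generate_microclimate",
    "generate_drying_experiment",
    "drying_params_from_calibration",
    "generate_raman_cube",
    "generate_thickness_dataset",
]


# ---------------------------------------------------------------------------
# Calibrations (field-study group parameters used as ground truth)
# ---------------------------------------------------------------------------

#: g_min group (mean, SD) in mmol m^-2 s^-1 per exposure temperature (degC).
GMIN_CALIBRATION_N: dict[float, tuple[float, float]] = {
    25.0: (1.78, 0.32),
    38.0: (2.58, 0.75),
    43.0: (6.91, 1.20),
}
GMIN_CALIBRATION_S: dict[float, tuple[float, float]] = {
    25.0: (1.39, 0.46),
    38.0: (1.86, 0.46),
    43.0: (3.53, 1.21),
}

#: Site-level cuticle thickness (mean, SD) in um.
THICKNESS_SITE: dict[str, tuple[float, float]] = {"N": (10.9, 4.4), "S": (15.9, 4.2)}

#: Per-side thickness means (um) consistent with the site means and the
#: reported pairwise cell differences (adaxial-abaxial 3.17 um at S, etc.).
THICKNESS_SIDE_N: dict[str, tuple[float, float]] = {
    "adaxial": (9.965, 4.4),
    "abaxial": (11.835, 4.4),
}
THICKNESS_SIDE_S: dict[str, tuple[float, float]] = {
    "adaxial": (17.485, 4.2),
    "abaxial": (14.315, 4.2),
}


@dataclass
class SiteScenario:
    """Everything needed to emulate one slope site."""

    name: str
    latitude: float  # degrees
    longitude: float  # degrees
    normal_elevation: float  # degrees, canopy surface normal
    normal_azimuth: float  # degrees, 0 = north, clockwise
    leaf_temp_mean: float  # degC, base of the diurnal cycle
    leaf_temp_amplitude: float  # K
    leaf_temp_noise_sd: float  # K, per sample per sensor
    cloudiness: float  # [0, 1], scales per-day clearness reduction
    gmin_calibration: dict[float, tuple[float, float]] = field(default_factory=dict)
    thickness_calibration: dict[str, tuple[float, float]] = field(default_factory=dict)
    # structure beyond the bare sinusoid
    day_effect_sd: float = 0.0  # K, day-to-day offset (frost/heat structure)
    radiative_heating: float = 0.0  # K, clear-sky midday leaf heating above air
    wind_mean: float = 1.0  # m s^-1
    wind_sd: float = 0.8  # m s^-1
    n_sensors: int = 12
    utc_offset_hours: float = 2.0
    clear_sky_beam_ppfd: float = 2400.0  # umol m^-2 s^-1, beam-normal

    def __post_init__(self) -> None:
        if not (0.0 <= self.cloudiness <= 1.0):
            raise ValueError("cloudiness must be in [0, 1]")
        for sd in (self.leaf_temp_noise_sd, self.day_effect_sd, self.wind_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        for cal in (self.gmin_calibration, self.thickness_calibration):
            for mean, sd in cal.values():
                if mean <= 0:
                    raise ValueError("calibration means must be positive")
                if sd < 0:
                    raise ValueError("calibration SDs must be non-negative")


N_SITE = SiteScenario(
    name="N",
    latitude=47.208056,
    longitude=11.461667,
    normal_elevation=45.0,
    normal_azimuth=350.0,
    leaf_temp_mean=10.3,
    leaf_temp_amplitude=9.0,
    leaf_temp_noise_sd=0.5,
    cloudiness=0.45,
    gmin_calibration=GMIN_CALIBRATION_N,
    thickness_calibration=THICKNESS_SIDE_N,
    day_effect_sd=3.0,
    radiative_heating=15.0,
    wind_mean=0.89,
    wind_sd=0.9,
)

S_SITE = SiteScenario(
    name="S",
    latitude=47.209444,
    longitude=11.463889,
    normal_elevation=35.0,
    normal_azimuth=135.0,
    leaf_temp_mean=13.8,
    leaf_temp_amplitude=10.0,
    leaf_temp_noise_sd=0.5,
    cloudiness=0.35,
    gmin_calibration=GMIN_CALIBRATION_S,
    thickness_calibration=THICKNESS_SIDE_S,
    day_effect_sd=3.0,
    radiative_heating=25.0,
    wind_mean=1.05,
    wind_sd=1.2,
)


# ---------------------------------------------------------------------------
# Microclimate
# ---------------------------------------------------------------------------

def generate_microclimate(
    scenario: SiteScenario,
    start: date | str,
    end: date | str,
    step_minutes: int = 1,
    seed: int = 0,
) -> MicroclimateSeries:
    """Diurnal microclimate series for one site (site-local timestamps).

    Horizontal PPFD is constructed as ``beam * clearness(day) *
    max(0, sin(solar elevation))`` so that the downstream sine correction
    recovers the beam value exactly above the correction cutoff; the beam
    series is stored as ground truth.  Leaf temperature is a diurnal
    sinusoid (peak mid-afternoon) plus a per-day offset, a clear-sky
    radiative heating term and white sensor noise.
    """
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    if start_ts >= end_ts:
        raise ValueError("start must precede end")
    if step_minutes < 1:
        raise ValueError("step must be at least 1 minute")
    rng = np.random.default_rng(seed)

    ts = pd.date_range(start_ts, end_ts, freq=f"{step_minutes}min", inclusive="left")
    ts_utc = ts - pd.Timedelta(hours=scenario.utc_offset_hours)
    _, elev = solar_positions(ts_utc, scenario.latitude, scenario.longitude)
    sin_el = np.clip(np.sin(np.deg2rad(elev)), 0.0, None)

    days = ts.normalize()
    unique_days = days.unique()
    n_days = len(unique_days)
    day_map = {d: i for i, d in enumerate(unique_days)}
    idx = np.fromiter((day_map[d] for d in days), count=len(days), dtype=int)

    clearness_day = 1.0 - scenario.cloudiness * rng.uniform(0.0, 1.0, size=n_days)
    day_offset = rng.normal(0.0, scenario.day_effect_sd, size=n_days) \
        if scenario.day_effect_sd > 0 else np.zeros(n_days)
    clearness = clearness_day[idx]

    beam = scenario.clear_sky_beam_ppfd * clearness
    ppfd = beam * sin_el

    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    diurnal = np.sin(2.0 * np.pi * (hours - 8.0) / 24.0)
    base_temp = (
        scenario.leaf_temp_mean
        + day_offset[idx]
        + scenario.leaf_temp_amplitude * diurnal
        + scenario.radiative_heating * clearness * sin_el**2
    )
    noise = (
        rng.normal(0.0, scenario.leaf_temp_noise_sd, size=(len(ts), scenario.n_sensors))
        if scenario.leaf_temp_noise_sd > 0
        else np.zeros((len(ts), scenario.n_sensors))
    )
    leaf_temps = base_temp[:, None] + noise

    wind_diurnal = 1.0 + 0.4 * np.sin(2.0 * np.pi * (hours - 14.0) / 24.0)
    wind = np.maximum(
        0.0,
        scenario.wind_mean * wind_diurnal
        + (rng.normal(0.0, scenario.wind_sd, size=len(ts)) if scenario.wind_sd > 0 else 0.0),
    )

    return MicroclimateSeries(
        timestamps=ts,
        leaf_temperatures=leaf_temps,
        wind_speed=wind,
        ppfd_horizontal=ppfd,
        site_name=scenario.name,
        latitude=scenario.latitude,
        longitude=scenario.longitude,
        normal_elevation=scenario.normal_elevation,
        normal_azimuth=scenario.normal_azimuth,
        utc_offset_hours=scenario.utc_offset_hours,
        beam_ppfd=beam,
    )


# ---------------------------------------------------------------------------
# Forward drying model
# ---------------------------------------------------------------------------

@dataclass
class DryingForwardParams:
    """Parameters of the forward bench-drying conductance model.

    Total conductance is a constant cuticular term plus an exponentially
    decaying stomatal term, ``g(t) = true_gmin + stomatal_g0 *
    exp(-t/tau)``; once a set fraction of the losable water pool is gone,
    the cuticular term declines linearly with the remaining pool (tissue
    desiccation).
    """

    true_gmin: float  # mmol m^-2 s^-1
    stomatal_g0: float = 8.0  # mmol m^-2 s^-1 at t = 0
    closure_time_constant: float = 0.8  # hours
    ambient_temp: float = 25.0  # degC
    relative_humidity: float = 35.0  # percent
    pressure: float = 101.3  # kPa
    leaf_area: float = 5.4e-4  # m^2, projected one-sided
    initial_mass: float = 0.4  # g
    losable_water_fraction: float = 0.45  # of initial mass
    desiccation_onset_fraction: float = 0.85  # of the losable pool
    balance_noise_sd: float = 1e-4  # g (0.1 mg)
    interval: float = 20.0  # minutes between weighings
    duration: float = 24.0  # hours
    seed: int = 0

    def __post_init__(self) -> None:
        positives = dict(
            true_gmin=self.true_gmin,
            closure_time_constant=self.closure_time_constant,
            pressure=self.pressure,
            leaf_area=self.leaf_area,
            initial_mass=self.initial_mass,
            losable_water_fraction=self.losable_water_fraction,
            interval=self.interval,
            duration=self.duration,
        )
        for name, v in positives.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not np.isfinite(self.stomatal_g0) or self.stomatal_g0 < 0:
            raise ValueError("stomatal_g0 must be finite and non-negative")
        if not (0.0 < self.relative_humidity < 100.0):
            raise ValueError("relative humidity must be in (0, 100)")
        if not (0.0 < self.desiccation_onset_fraction <= 1.0):
            raise ValueError("desiccation_onset_fraction must be in (0, 1]")
        if self.balance_noise_sd < 0:
            raise ValueError("balance noise SD must be non-negative")


def generate_drying_experiment(
    params: DryingForwardParams, sample_id: str = "synthetic", metadata: dict | None = None
) -> DryingExperiment:
    """Simulate a repeated-weighing drying record from the forward model.

    The conductance is integrated in 1-minute substeps; each weighing is the
    true cumulative mass plus Gaussian balance noise.  Ground truth (per
    interval mean conductance, phase labels, true g_min) is stored in the
    experiment's metadata.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_intervals = int(round(p.duration * 60.0 / p.interval))
    if n_intervals < 3:
        raise ValueError("duration too short for the weighing interval")

    vpd = vpd_mole_fraction(p.ambient_temp, p.ambient_temp, p.relative_humidity, p.pressure)
    # mass flux per unit conductance [g per (mmol m^-2 s^-1) per second]
    flux_per_g = 1e-3 * vpd * p.leaf_area * MOLAR_MASS_WATER

    pool = p.losable_water_fraction * p.initial_mass
    onset = p.desiccation_onset_fraction * pool

    sub_per_interval = max(1, int(round(p.interval)))  # ~1-min substeps
    dt_sub_s = p.interval * 60.0 / sub_per_interval
    tau_s = p.closure_time_constant * 3600.0

    masses = np.empty(n_intervals + 1)
    masses[0] = p.initial_mass
    true_g = np.empty(n_intervals)
    phase = np.empty(n_intervals, dtype=object)
    lost = 0.0
    desiccating = False
    t = 0.0
    for i in range(n_intervals):
        g_sum = 0.0
        interval_desiccating = desiccating
        for _ in range(sub_per_interval):
            if lost >= onset:
                desiccating = True
                interval_desiccating = True
            if desiccating:
                remaining = max(pool - lost, 0.0)
                g_cut = p.true_gmin * remaining / max(pool - onset, 1e-12)
            else:
                g_cut = p.true_gmin
            g_now = g_cut + p.stomatal_g0 * np.exp(-t / tau_s)
            dm = g_now * flux_per_g * dt_sub_s
            lost += dm
            g_sum += g_now
            t += dt_sub_s
        true_g[i] = g_sum / sub_per_interval
        masses[i + 1] = p.initial_mass - lost
        t_mid_s = (i + 0.5) * p.interval * 60.0
        stomatal_frac = p.stomatal_g0 * np.exp(-t_mid_s / tau_s) / p.true_gmin
        if interval_desiccating:
            phase[i] = "desiccated"
        elif stomatal_frac > 0.01:
            phase[i] = "stomatal"
        else:
            phase[i] = "plateau"

    if masses[-1] <= 0:
        raise ValueError("parameters dry the sample out completely; shorten duration")
    if p.balance_noise_sd > 0:
        masses = masses + rng.normal(0.0, p.balance_noise_sd, size=masses.shape)

    timestamps = pd.date_range(
        "2023-07-01 08:00", periods=n_intervals + 1, freq=f"{int(round(p.interval * 60))}s"
    )
    meta = {
        "true_gmin": p.true_gmin,
        "true_g_intervals": true_g,
        "phase_truth": phase,
        "forward_params": p,
    }
    if metadata:
        meta.update(metadata)
    return DryingExperiment(
        sample_id=sample_id,
        timestamps=timestamps,
        masses=masses,
        ambient_temp=p.ambient_temp,
        relative_humidity=p.relative_humidity,
        pressure=p.pressure,
        projected_leaf_area=p.leaf_area,
        metadata=meta,
    )


def drying_params_from_calibration(
    scenario: SiteScenario,
    temperature: float,
    rng: np.random.Generator,
    **overrides,
) -> DryingForwardParams:
    """Forward parameters for one twig of a calibrated site x temperature cell.

    The twig's true g_min is drawn from the scenario's calibration (mean,
    SD) at the given exposure temperature, truncated at a small positive
    floor; ambient temperature is set to the exposure temperature.
    """
    if temperature not in scenario.gmin_calibration:
        raise KeyError(
            f"no g_min calibration at {temperature} degC for site {scenario.name}"
        )
    mean, sd = scenario.gmin_calibration[temperature]
    true_gmin = max(float(rng.normal(mean, sd)), 0.05)
    defaults = dict(
        true_gmin=true_gmin,
        ambient_temp=temperature,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    defaults.update(overrides)
    return DryingForwardParams(**defaults)


# ---------------------------------------------------------------------------
# Raman cubes
# ---------------------------------------------------------------------------

#: Endmember band definitions: label -> ((center cm^-1, relative amplitude), ...)
ENDMEMBER_BANDS: dict[str, tuple[tuple[float, float], ...]] = {
    "cutin": ((1443.0, 1.0), (1306.0, 0.8)),
    "triterpenoids": (
        (463.0, 0.5),
        (532.0, 0.6),
        (564.0, 0.5),
        (683.0, 0.6),
        (729.0, 0.8),
        (746.0, 1.0),
    ),
    "flavonoids": ((1570.0, 1.0), (1250.0, 0.8), (1607.0, 0.9)),
    "cinnamic_acid": ((1630.0, 1.0), (1170.0, 0.8)),
    "crystalline_alkanes": ((1064.0, 0.8), (1133.0, 0.7), (1297.0, 1.0)),
    "anthocyanins": ((631.0, 0.7), (1630.0, 1.0)),
}


def endmember_spectrum(
    label: str, wavenumbers: np.ndarray, fwhm: float = 12.0
) -> np.ndarray:
    """Sum-of-Gaussians endmember at the band-assignment positions."""
    if label not in ENDMEMBER_BANDS:
        raise KeyError(f"unknown endmember {label!r}; known: {sorted(ENDMEMBER_BANDS)}")
    wn = np.asarray(wavenumbers, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.zeros_like(wn)
    for center, amp in ENDMEMBER_BANDS[label]:
        out += amp * np.exp(-((wn - center) ** 2) / (2.0 * sigma**2))
    return out


def generate_raman_cube(
    layers: list[tuple[float, str, float]],
    pixel_size: float = 0.3,
    wavenumber_range: tuple[float, float] = (100.0, 2000.0),
    spacing: float = 1.0,
    baseline_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    cosmic_ray_rate: float = 0.0,
    seed: int = 0,
    width_pixels: int = 20,
    fwhm: float = 12.0,
) -> RamanCube:
    """Layered cuticle cross-section cube with known composition.

    ``layers`` is a top-to-bottom list of (thickness um, endmember label,
    concentration); each layer occupies ``round(thickness / pixel_size)``
    rows of the grid.  Per-pixel spectra are the layer's scaled endmember
    plus a smooth quadratic baseline, white noise, and 1-2-channel cosmic
    rays at ``cosmic_ray_rate`` expected spikes per spectrum.  Layer
    geometry and the pure endmember spectra are stored as ground truth in
    the cube metadata.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    if any(th <= 0 for th, _, _ in layers):
        raise ValueError("layer thicknesses must be positive")
    lo, hi = wavenumber_range
    wn = np.arange(lo, hi + spacing / 2, spacing)
    for _, label, _ in layers:
        for center, _amp in ENDMEMBER_BANDS[label]:
            if not (lo <= center <= hi):
                raise ValueError(
                    f"wavenumber range {wavenumber_range} excludes the "
                    f"{label!r} band at {center} cm^-1"
                )

    rng = np.random.default_rng(seed)
    rows_per_layer = [int(round(th / pixel_size)) for th, _, _ in layers]
    ny = sum(rows_per_layer)
    nx = width_pixels

    x = (wn - lo) / (hi - lo)
    baseline = baseline_amplitude * (0.3 + 0.7 * x + 0.5 * x**2)

    cube = np.empty((ny, nx, len(wn)))
    labels = np.empty(ny, dtype=object)
    layer_rows = []
    row = 0
    endmembers = {}
    for (th, label, conc), nrow in zip(layers, rows_per_layer):
        if label not in endmembers:
            endmembers[label] = endmember_spectrum(label, wn, fwhm=fwhm)
        pure = conc * endmembers[label]
        cube[row : row + nrow] = pure[None, None, :] + baseline[None, None, :]
        labels[row : row + nrow] = label
        layer_rows.append({"label": label, "row_start": row, "row_end": row + nrow,
                           "thickness_um": th, "concentration": conc})
        row += nrow

    if noise_sd > 0:
        cube += rng.normal(0.0, noise_sd, size=cube.shape)
    if cosmic_ray_rate > 0:
        signal_peak = max(float(np.max(cube)), 1e-9)
        for p in range(ny * nx):
            n_spikes = rng.poisson(cosmic_ray_rate)
            iy, ix = divmod(p, nx)
            for _ in range(n_spikes):
                ch = int(rng.integers(0, len(wn)))
                width = int(rng.integers(1, 3))
                amp = (20.0 + 40.0 * rng.uniform()) * max(noise_sd, 0.02 * signal_peak)
                cube[iy, ix, ch : ch + width] += amp

    return RamanCube(
        wavenumbers=wn,
        intensities=cube,
        pixel_size=pixel_size,
        metadata={
            "layer_rows": layer_rows,
            "row_labels": labels,
            "true_endmembers": endmembers,
            "noise_sd": noise_sd,
            "baseline_amplitude": baseline_amplitude,
            "excitation_nm": 785.0,
            "integration_time_s": 0.1,
        },
    )


# ---------------------------------------------------------------------------
# Thickness datasets
# ---------------------------------------------------------------------------

def generate_thickness_dataset(
    calibrations: dict, seed: int = 0
) -> ThicknessDataset:
    """Normally distributed thickness groups, truncated at zero.

    ``calibrations`` maps either ``(site, side)`` tuples or plain site
    labels to ``(mean um, SD um, n)``.  Values are drawn independently per
    group and floored at a vanishing positive thickness (truncation; at the
    calibrated means/SDs the effect on group means is negligible).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key, (mean, sd, n) in calibrations.items():
        if mean <= 0:
            raise ValueError(f"non-positive mean for group {key!r}")
        if n < 2:
            raise ValueError(f"need n >= 2 per group, got {n} for {key!r}")
        site, side = key if isinstance(key, tuple) else (key, "pooled")
        values = np.maximum(rng.normal(mean, sd, size=int(n)), 1e-9)
        for v in values:
            rows.append({"site": site, "side": side, "thickness": float(v)})
    return ThicknessDataset(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Delimited-text writers / scenario IO
# ---------------------------------------------------------------------------

def write_microclimate_csv(series: MicroclimateSeries, path) -> None:
    df = series.to_frame()
    df.index.name = "timestamp"
    df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")


def write_drying_csv(exp: DryingExperiment, path) -> None:
    df = exp.to_frame()
    df.index.name = "timestamp"
    df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")


def scenario_to_dict(s: SiteScenario) -> dict:
    return {
        "name": s.name,
        "latitude": s.latitude,
        "longitude": s.longitude,
        "normal_elevation": s.normal_elevation,
        "normal_azimuth": s.normal_azimuth,
        "leaf_temp_mean": s.leaf_temp_mean,
        "leaf_temp_amplitude": s.leaf_temp_amplitude,
        "leaf_temp_noise_sd": s.leaf_temp_noise_sd,
        "cloudiness": s.cloudiness,
        "gmin_calibration": {str(k): list(v) for k, v in s.gmin_calibration.items()},
        "thickness_calibration": {
            k: list(v) for k, v in s.thickness_calibration.items()
        },
        "day_effect_sd": s.day_effect_sd,
        "radiative_heating": s.radiative_heating,
        "wind_mean": s.wind_mean,
        "wind_sd": s.wind_sd,
        "n_sensors": s.n_sensors,
        "utc_offset_hours": s.utc_offset_hours,
        "clear_sky_beam_ppfd": s.clear_sky_beam_ppfd,
    }


def scenario_from_dict(d: dict) -> SiteScenario:
    d = dict(d)
    d["gmin_calibration"] = {
        float(k): tuple(v) for k, v in d.get("gmin_calibration", {}).items()
    }
    d["thickness_calibration"] = {
        k: tuple(v) for k, v in d.get("thickness_calibration", {}).items()
    }
    return SiteScenario(**d)
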