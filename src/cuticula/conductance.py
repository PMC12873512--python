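"""Minimum diffusive conductance (g_min) from bench-drying mass loss.

The mass-loss-of-detached-leaves (MLD) technique repeatedly weighs a
stem-sealed twig while it dries on the bench.  Each mass decrement over a
weighing interval is the water transpired; dividing by molar mass, leaf area
and interval length yields the transpiration rate E, and dividing E by the
mole-fraction vapour pressure deficit (VPD) of the ambient air yields the
diffusive conductance g for that interval:

    E = dm / (M_w * A * dt)          [mmol m^-2 s^-1]
    g = E / VPD_mol                  [mmol m^-2 s^-1]

A drying curve has three phases: an initial rapid decline while stomata
close, a long plateau of constant low conductance (the cuticle-dominated
phase, whose mean is g_min), and a terminal decline once the tissue has
desiccated and no longer sustains saturation inside the leaf.  g_min is the
mean conductance over the detected plateau.

Stomata are assumed fully closed on the plateau, and leaf temperature is
taken equal to ambient temperature during bench drying; estimates are
therefore reported as g_min rather than strictly cuticular conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_MASS_WATER",
    "DryingExperiment",
    "ConductanceSeries",
    "GminEstimate",
    "PlateauNotFoundError",
    "saturation_vapour_pressure",
    "vpd_mole_fraction",
    "conductance_series",
    "detect_plateau",
    "estimate_gmin",
]

#: Molar mass of water [g mol^-1].
MOLAR_MASS_WATER = 18.015


class PlateauNotFoundError(RuntimeError):
    """Raised when a drying record has no usable constant-conductance phase."""


@dataclass
class DryingExperiment:
    """Repeated-weighing record of a sealed twig during bench drying.

    Ambient conditions may be scalars (constant over the run) or per-weighing
    arrays; ``projected_leaf_area`` is the one-sided projected area in m².
    """

    sample_id: str
    timestamps: pd.DatetimeIndex
    masses: np.ndarray  # g
    ambient_temp: np.ndarray | float  # degC
    relative_humidity: np.ndarray | float  # percent
    pressure: np.ndarray | float  # kPa
    projected_leaf_area: float  # m^2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.masses) != len(self.timestamps):
            raise ValueError("masses and timestamps length mismatch")
        if len(self.masses) < 4:
            raise ValueError("need at least 4 weighings")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.projected_leaf_area <= 0:
            raise ValueError("leaf area must be positive")
        rh = np.asarray(self.relative_humidity, dtype=float)
        if np.any(rh <= 0) or np.any(rh >= 100):
            raise ValueError("relative humidity must be in (0, 100)")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.timestamps)
        return pd.DataFrame(
            {
                "mass_g": self.masses,
                "ambient_temp_C": np.broadcast_to(
                    np.asarray(self.ambient_temp, dtype=float), (n,)
                ),
                "relative_humidity_pct": np.broadcast_to(
                    np.asarray(self.relative_humidity, dtype=float), (n,)
                ),
                "pressure_kPa": np.broadcast_to(
                    np.asarray(self.pressure, dtype=float), (n,)
                ),
            },
            index=self.timestamps,
        )


@dataclass
class ConductanceSeries:
    """Per-interval diffusive conductance derived from a drying record."""

    midpoints: pd.DatetimeIndex
    elapsed_hours: np.ndarray  # interval midpoints, hours since first weighing
    g: np.ndarray  # mmol m^-2 s^-1
    phase: np.ndarray  # 'stomatal' | 'plateau' | 'desiccated' | 'unassigned'

    def __len__(self) -> int:
        return len(self.g)


@dataclass
class GminEstimate:
    """Plateau mean of the conductance series."""

    gmin: float  # mmol m^-2 s^-1
    sd: float
    plateau_start: int
    plateau_end: int  # exclusive
    n_intervals: int


def saturation_vapour_pressure(temp_c) -> np.ndarray | float:
    """Saturation water vapour pressure [kPa] by the Magnus approximation.

    ``es(T) = 0.61094 * exp(17.625 T / (T + 243.04))`` with T in degC; valid
    over liquid water for roughly -40..60 degC.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < -40.0) or np.any(t > 60.0):
        raise ValueError("temperature outside -40..60 degC validity range")
    es = 0.61094 * np.exp(17.625 * t / (t + 243.04))
    return float(es) if es.ndim == 0 else es


def vpd_mole_fraction(leaf_temp_c, air_temp_c, rh_percent, pressure_kpa):
    """Mole-fraction vapour pressure deficit [mol mol^-1].

    Difference between the saturation mole fraction at leaf temperature
    (air inside the leaf assumed saturated) and the ambient vapour mole
    fraction, floored at zero.
    """
    rh = np.asarray(rh_percent, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be within [0, 100]")
    p = np.asarray(pressure_kpa, dtype=float)
    if np.any(p <= 50.0):
        raise ValueError("pressure must exceed 50 kPa")
    es_leaf = saturation_vapour_pressure(leaf_temp_c)
    es_air = saturation_vapour_pressure(air_temp_c)
    vpd = (np.asarray(es_leaf) - rh / 100.0 * np.asarray(es_air)) / p
    vpd = np.maximum(vpd, 0.0)
    return float(vpd) if vpd.ndim == 0 else vpd


def conductance_series(exp: DryingExperiment) -> ConductanceSeries:
    """Per-interval conductance g = E / VPD from consecutive weighings.

    Leaf temperature is taken equal to the concurrent ambient temperature;
    VPD is recomputed per interval from the ambient records bracketing it.
    """
    t = exp.timestamps
    if not t.is_monotonic_increasing or t.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    dt_s = np.diff(t.asi8) / 1e9
    dm = -np.diff(exp.masses)  # mass lost per interval, g

    n = len(exp.masses)
    temp = np.broadcast_to(np.asarray(exp.ambient_temp, dtype=float), (n,))
    rh = np.broadcast_to(np.asarray(exp.relative_humidity, dtype=float), (n,))
    p = np.broadcast_to(np.asarray(exp.pressure, dtype=float), (n,))
    # interval-mean ambient conditions
    temp_m = 0.5 * (temp[:-1] + temp[1:])
    rh_m = 0.5 * (rh[:-1] + rh[1:])
    p_m = 0.5 * (p[:-1] + p[1:])

    vpd = vpd_mole_fraction(temp_m, temp_m, rh_m, p_m)
    vpd = np.asarray(vpd)
    if np.any(vpd <= 0):
        raise ValueError("VPD is zero on at least one interval (saturated air)")

    # E in mmol m^-2 s^-1: dm[g] / (M_w[g/mol] A[m^2] dt[s]) * 1000
    e_mmol = dm / (MOLAR_MASS_WATER * exp.projected_leaf_area * dt_s) * 1e3
    g = e_mmol / vpd

    mid_ns = t.asi8[:-1] + (np.diff(t.asi8) // 2)
    midpoints = pd.DatetimeIndex(mid_ns.astype("datetime64[ns]"))
    elapsed_h = (mid_ns - t.asi8[0]) / 3.6e12
    return ConductanceSeries(
        midpoints=midpoints,
        elapsed_hours=elapsed_h,
        g=g,
        phase=np.full(len(g), "unassigned", dtype=object),
    )


def _smooth(g: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if window <= 1:
        return g.astype(float)
    half = window // 2
    out = np.empty_like(g, dtype=float)
    for i in range(len(g)):
        lo = max(0, i - half)
        hi = min(len(g), i + half + 1)
        out[i] = g[lo:hi].mean()
    return out


def detect_plateau(
    series: ConductanceSeries,
    rel_slope_threshold: float = 0.02,
    min_run: int = 6,
    smooth_window: int | None = None,
) -> tuple[int, int]:
    """Locate the constant-conductance phase of a drying record.

    The conductance series is smoothed with a centred moving average and the
    relative change of the smoothed series per hour is evaluated over a
    matching lag.  The plateau is the longest contiguous run of intervals,
    after the initial stomatal decline, whose relative slope magnitude stays
    below ``rel_slope_threshold`` (per hour).  A persistent strictly
    monotone decline at the very end of the record (tissue desiccation,
    at least ``min_run`` intervals long) is excluded before the search.

    ``smooth_window`` (points) sets both the moving-average span and the
    slope lag; when ``None``, it is chosen adaptively from a robust estimate
    of the per-interval noise so that noise-induced apparent slopes stay
    below the threshold.  Balance noise is zero-mean in the mass decrements,
    so the plateau mean is insensitive to the exact run bounds as long as
    they lie inside the true constant phase.

    Returns ``(start, end)`` interval indices (end exclusive).  Raises
    :class:`PlateauNotFoundError` when no qualifying run of at least
    ``min_run`` intervals exists — the experiment is unusable.
    """
    g = np.asarray(series.g, dtype=float)
    t_h = np.asarray(series.elapsed_hours, dtype=float)
    n = len(g)
    if n < min_run:
        raise PlateauNotFoundError("series shorter than min_run")
    dt_h = float(np.median(np.diff(t_h))) if n > 1 else 1.0

    if smooth_window is None:
        # Robust per-interval noise (white noise doubles into first
        # differences); lag k such that the noise-induced relative slope
        # ~ cv*sqrt(2)/(k^1.5 dt) sits safely below the threshold.
        noise_sd = 1.4826 * float(np.median(np.abs(np.diff(g)))) / np.sqrt(2.0)
        # Scale of the signal near the plateau: use the first half of the
        # record (stomatal + plateau phases); a fully desiccated tail of
        # near-zero conductances would otherwise drag the scale to zero.
        scale = max(float(np.median(np.abs(g[: max(min_run, n // 2)]))), 1e-12)
        cv = noise_sd / scale
        k = int(np.ceil((1.5 * cv * np.sqrt(2.0) / (dt_h * rel_slope_threshold)) ** (2.0 / 3.0)))
        k = max(1, min(k, max(1, (n - min_run) // 2)))
    else:
        k = max(1, int(smooth_window))
    s = _smooth(g, k)

    # Exclude a persistent terminal monotone decline (>= min_run intervals).
    end_limit = n
    j = n - 1
    while j > 0 and s[j] < s[j - 1]:
        j -= 1
    if n - j >= min_run:
        end_limit = j

    # Transition i spans points i..i+k; it qualifies when the relative
    # change of the smoothed series per hour stays below threshold.
    n_trans = n - k
    ok = np.zeros(max(n_trans, 0), dtype=bool)
    for i in range(n_trans):
        if i + k >= end_limit:
            break
        mid = 0.5 * (s[i] + s[i + k])
        if mid <= 0:
            continue
        span_h = t_h[i + k] - t_h[i]
        ok[i] = abs(s[i + k] - s[i]) / (mid * span_h) <= rel_slope_threshold

    best = (0, 0)  # plateau candidate [start, end) in point indices
    i = 0
    while i < len(ok):
        if ok[i]:
            j2 = i
            while j2 < len(ok) and ok[j2]:
                j2 += 1
            start, end = i, (j2 - 1) + k + 1
            if end - start > best[1] - best[0]:
                best = (start, end)
            i = j2
        else:
            i += 1
    if best[1] - best[0] < min_run:
        raise PlateauNotFoundError(
            "no constant-conductance run of length >= "
            f"{min_run} below {rel_slope_threshold:.3g}/h"
        )
    return best


def estimate_gmin(
    exp: DryingExperiment,
    rel_slope_threshold: float = 0.02,
    min_run: int = 6,
    smooth_window: int | None = None,
) -> GminEstimate:
    """Mean conductance over the detected plateau of a drying experiment."""
    series = conductance_series(exp)
    start, end = detect_plateau(
        series,
        rel_slope_threshold=rel_slope_threshold,
        min_run=min_run,
        smooth_window=smooth_window,
    )
    series.phase[:start] = "stomatal"
    series.phase[start:end] = "plateau"
    series.phase[end:] = "desiccated"
    g_plateau = series.g[start:end]
    gmin = float(np.mean(g_plateau))
    if gmin <= 0:
        raise PlateauNotFoundError("non-positive plateau mean; record unusable")
    return GminEstimate(
        gmin=gmin,
        sd=float(np.std(g_plateau, ddof=1)),
        plateau_start=start,
        plateau_end=end,
        n_intervals=end - start,
    )
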