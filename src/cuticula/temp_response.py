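"""Exponential temperature response of minimum diffusive conductance.

Cuticular water permeability rises steeply with temperature; over the
sublethal range the response of g_min is well described by a general
exponential with a temperature-independent floor:

    g_min(T) = g_min(0 degC) + A * exp(R0 * T)

where ``g_min(0 degC)`` is the conductance extrapolated to 0 degC
[mmol m^-2 s^-1], ``A`` scales the magnitude of the temperature response
[mmol m^-2 s^-1] and ``R0`` [degC^-1] positions the upturn along the
temperature axis.  All three parameters are constrained non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["TemperatureResponseModel", "fit_temperature_response", "predict"]


@dataclass
class TemperatureResponseModel:
    gmin0: float  # mmol m^-2 s^-1 at 0 degC
    A: float  # mmol m^-2 s^-1
    R0: float  # degC^-1
    residual_sse: float
    n_points: int

    def predict(self, temperature):
        return predict(self, temperature)


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    gmin0, a, r0 = params
    return gmin0 + a * np.exp(r0 * t)


def fit_temperature_response(points) -> TemperatureResponseModel:
    """Nonlinear least-squares fit of the exponential response.

    Parameters
    ----------
    points : sequence of (temperature degC, gmin) pairs, or a 2-column array.

    The fit needs at least 4 points on at least 3 distinct temperatures
    (three parameters plus one residual degree of freedom).  Initialisation
    is deterministic: ``gmin0`` starts at the minimum observed conductance,
    ``R0`` at the slope of ``log(g - 0.9 min g)`` against temperature and
    ``A`` at the back-transformed intercept; bounds keep all parameters
    non-negative.  Non-convergence raises rather than returning silently.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): temperature, gmin")
    t, g = pts[:, 0], pts[:, 1]
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct temperatures")

    gmin_obs = float(np.min(g))
    shifted = g - 0.9 * gmin_obs
    pos = shifted > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(shifted[pos]), 1)
        r0_init = max(slope, 1e-6)
        a_init = max(np.exp(intercept), 1e-12)
    else:  # flat data
        r0_init = 1e-3
        a_init = max(np.mean(g) - gmin_obs, 1e-12)
    x0 = np.array([max(gmin_obs, 1e-12), a_init, r0_init])

    res = least_squares(
        lambda p: _model(p, t) - g,
        x0,
        bounds=(np.zeros(3), np.full(3, np.inf)),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=20000,
    )
    if not res.success:
        raise RuntimeError(f"temperature-response fit did not converge: {res.message}")
    gmin0, a, r0 = res.x
    return TemperatureResponseModel(
        gmin0=float(gmin0),
        A=float(a),
        R0=float(r0),
        residual_sse=float(2.0 * res.cost),
        n_points=len(t),
    )


def predict(model: TemperatureResponseModel, temperature):
    """Evaluate g_min(T) = gmin0 + A exp(R0 T).

    The response was characterised for T > 0 degC; evaluation outside that
    domain emits a warning but still returns the functional value.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        warnings.warn(
            "temperature outside the characterised domain (T > 0 degC)",
            stacklevel=2,
        )
    out = model.gmin0 + model.A * np.exp(model.R0 * t)
    return float(out) if out.ndim == 0 else out
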