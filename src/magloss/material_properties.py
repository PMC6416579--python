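"""Temperature-dependent carrier-fluid properties from sparse measurements.

Viscosity and density of the carrier enter the Brownian relaxation time and
are typically measured at only a few temperatures.  Viscosity of oils is
strongly non-Arrhenius, so with exactly three points a Vogel-Fulcher-Tammann
law

    eta(T) = A * exp(B / (T - T0))        (T in kelvin)

is fitted *exactly* through them (closed form); with two points, or when the
VFT solution is degenerate (T0 inside or above the evaluation range), the
fit falls back to an Arrhenius least-squares model ``A * exp(B/T)``.
Density is fitted as an ordinary straight line in temperature.

Interfaces accept degrees Celsius; all physics inside is in kelvin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CELSIUS_ZERO, celsius_to_kelvin

__all__ = [
    "PropertyPoints",
    "PropertyModel",
    "fit_viscosity",
    "fit_density",
    "evaluate",
    "DEFAULT_VALID_RANGE_C",
]

DEFAULT_VALID_RANGE_C = (0.0, 100.0)

# VFT divergence temperature must stay safely below the evaluation range
_T0_MARGIN_K = 5.0


@dataclass
class PropertyPoints:
    """Measured property values at a few temperatures (deg C)."""

    temperatures: np.ndarray  # deg C, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.size != self.values.size:
            raise ValueError("temperatures and values must have the same length")
        if self.temperatures.size < 2:
            raise ValueError("at least two measurement points are required")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class PropertyModel:
    """Fitted property law with its validity interval.

    kind is one of "viscosity-VFT", "viscosity-Arrhenius", "density-linear";
    params holds the model coefficients (VFT: A, B, T0 with B, T0 in K;
    Arrhenius: A, B; linear: a, b per deg C).
    """

    kind: str
    params: dict
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE_C
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _vft_exact(T_K: np.ndarray, eta: np.ndarray) -> dict | None:
    """Closed-form VFT through three points; None when degenerate."""
    y = np.log(eta)
    T1, T2, T3 = T_K
    y1, y2, y3 = y
    if math.isclose(y2, y3, rel_tol=0, abs_tol=1e-15):
        return None
    r = (y1 - y2) / (y2 - y3)
    denom = (T2 - T1) - r * (T3 - T2)
    if abs(denom) < 1e-12:
        return None
    T0 = ((T2 - T1) * T3 - r * (T3 - T2) * T1) / denom
    if T0 >= CELSIUS_ZERO + DEFAULT_VALID_RANGE_C[0] - _T0_MARGIN_K:
        return None  # divergence would sit in/near the evaluation range
    B = (y1 - y2) / (1.0 / (T1 - T0) - 1.0 / (T2 - T0))
    A = math.exp(y1 - B / (T1 - T0))
    return {"A": A, "B": B, "T0": T0}


def fit_viscosity(points: PropertyPoints) -> PropertyModel:
    """Fit the viscosity law (exact 3-point VFT, Arrhenius fallback)."""
    if np.any(points.values <= 0):
        raise ValueError("viscosity values must be positive")
    if np.any(np.diff(points.values) > 0):
        warnings.warn(
            "viscosity increases with temperature at some points; "
            "fitting anyway", stacklevel=2,
        )
    T_K = celsius_to_kelvin(points.temperatures)
    if points.values.size == 3:
        params = _vft_exact(T_K, points.values)
        if params is not None:
            model = PropertyModel("viscosity-VFT", params)
            model.residuals = evaluate(model, points.temperatures) - points.values
            return model
    # Arrhenius least squares: ln(eta) = ln(A) + B / T
    y = np.log(points.values)
    if np.allclose(y, y[0]):
        params = {"A": float(points.values[0]), "B": 0.0}
    else:
        B, logA = np.polyfit(1.0 / T_K, y, 1)
        params = {"A": float(math.exp(logA)), "B": float(B)}
    model = PropertyModel("viscosity-Arrhenius", params)
    model.residuals = evaluate(model, points.temperatures) - points.values
    return model


def fit_density(points: PropertyPoints) -> PropertyModel:
    """Ordinary linear fit ``rho(T) = a + b*T`` (T in deg C), with residuals."""
    b, a = np.polyfit(points.temperatures, points.values, 1)
    model = PropertyModel("density-linear", {"a": float(a), "b": float(b)})
    model.residuals = evaluate(model, points.temperatures) - points.values
    return model


def evaluate(model: PropertyModel, T_C):
    """Evaluate a fitted property model at temperature(s) in deg C."""
    T_arr = np.asarray(T_C, dtype=float)
    lo, hi = model.valid_range
    if np.any(T_arr < lo) or np.any(T_arr > hi):
        raise ValueError(
            f"temperature outside the model's valid range [{lo}, {hi}] deg C"
        )
    T_K = celsius_to_kelvin(T_arr)
    p = model.params
    if model.kind == "viscosity-VFT":
        out = p["A"] * np.exp(p["B"] / (T_K - p["T0"]))
    elif model.kind == "viscosity-Arrhenius":
        out = p["A"] * np.exp(p["B"] / T_K)
    elif model.kind == "density-linear":
        out = p["a"] + p["b"] * T_arr
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    return float(out) if np.isscalar(T_C) else out
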