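"""Calorimetric SAR estimation from temperature-time curves.

The measurement counterpart of the loss model: a sample of magnetic fluid is
exposed to the AC field and its temperature recorded with a fiber-optic
probe.  Just after switch-on, before losses to the surroundings matter, the
heating is adiabatic and

    SAR = c * rho * (dT/dt)_max / m_Fe

with c the specific heat capacity (J/(kg K)), rho the sample density
(kg/m^3) and m_Fe the mass of magnetic nanoparticles per unit volume of
fluid (kg/m^3).  The maximal temperature derivative usually occurs within
the first few seconds.

Pointwise finite differences amplify probe noise, so the default estimator
slides a least-squares straight line of fixed duration over the early part
of the record and takes the steepest window (a pointwise method is exposed
as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeatingCurve",
    "SlopeEstimate",
    "max_initial_slope",
    "sar_from_curve",
    "compare_model_measurement",
    "DEFAULT_WINDOW_S",
    "DEFAULT_HORIZON_S",
]

DEFAULT_WINDOW_S = 5.0
DEFAULT_HORIZON_S = 30.0

MERGE_KEYS = ["H_kA_per_m", "f_kHz", "mode"]


@dataclass
class HeatingCurve:
    """Temperature record of one calorimetric run plus sample properties."""

    t: np.ndarray  # s, strictly increasing
    T: np.ndarray  # deg C
    c: float  # J/(kg K)
    rho: float  # kg/m^3
    m_Fe: float  # kg of magnetic material per m^3 of fluid

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.t.size != self.T.size:
            raise ValueError("t and T must have the same length")
        if self.t.size < 3:
            raise ValueError("at least 3 samples are required")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.c <= 0 or self.rho <= 0 or self.m_Fe <= 0:
            raise ValueError("c, rho and m_Fe must be positive")

    def trimmed(self, t0: float) -> "HeatingCurve":
        """Drop pre-trigger samples and restart the clock at t0."""
        keep = self.t >= t0
        if keep.sum() < 3:
            raise ValueError("fewer than 3 samples remain after trimming")
        return HeatingCurve(self.t[keep] - t0, self.T[keep], self.c, self.rho, self.m_Fe)


@dataclass
class SlopeEstimate:
    """Maximal early-time temperature slope and the window that produced it."""

    dTdt_max: float  # K/s
    window: tuple[int, int]  # [start, stop) sample indices
    r_squared: float


def _rolling_slopes(t: np.ndarray, T: np.ndarray, n_w: int):
    """Least-squares slope and r^2 of every contiguous window of n_w samples.

    O(N) via prefix sums: slope = (n S_tT - S_t S_T) / (n S_tt - S_t^2).
    """
    # center both series for conditioning: the slope is shift-invariant
    t = t - t.mean()
    T = T - T.mean()
    # prefix sums with a leading zero so window sums are two lookups
    c_t = np.concatenate(([0.0], np.cumsum(t)))
    c_T = np.concatenate(([0.0], np.cumsum(T)))
    c_tt = np.concatenate(([0.0], np.cumsum(t * t)))
    c_TT = np.concatenate(([0.0], np.cumsum(T * T)))
    c_tT = np.concatenate(([0.0], np.cumsum(t * T)))
    n = t.size
    starts = np.arange(0, n - n_w + 1)
    stops = starts + n_w
    S_t = c_t[stops] - c_t[starts]
    S_T = c_T[stops] - c_T[starts]
    S_tt = c_tt[stops] - c_tt[starts]
    S_TT = c_TT[stops] - c_TT[starts]
    S_tT = c_tT[stops] - c_tT[starts]
    var_t = n_w * S_tt - S_t**2
    var_T = n_w * S_TT - S_T**2
    cov = n_w * S_tT - S_t * S_T
    slopes = cov / var_t
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var_T > 0, cov**2 / (var_t * var_T), 0.0)
    return starts, slopes, r2


def max_initial_slope(
    curve: HeatingCurve,
    window_seconds: float = DEFAULT_WINDOW_S,
    search_horizon_seconds: float = DEFAULT_HORIZON_S,
    method: str = "windowed",
) -> SlopeEstimate:
    """Maximum temperature slope over the early part of a heating curve.

    ``method="windowed"`` (default) slides a least-squares line of duration
    ``window_seconds`` over [0, search_horizon] and returns the steepest
    fit; ``method="pointwise"`` takes the maximum central finite difference
    on the same horizon (noise-amplifying, for diagnostics).
    """
    if search_horizon_seconds < window_seconds:
        raise ValueError(
            f"search horizon ({search_horizon_seconds} s) shorter than the "
            f"fit window ({window_seconds} s)"
        )
    t0 = curve.t[0]
    t = curve.t - t0
    in_horizon = t <= search_horizon_seconds
    t, T = t[in_horizon], curve.T[in_horizon]

    if method == "pointwise":
        dT = np.gradient(T, t)
        i = int(np.argmax(dT))
        return SlopeEstimate(float(dT[i]), (i, min(i + 2, t.size)), r_squared=1.0)
    if method != "windowed":
        raise ValueError(f"unknown slope method {method!r}")

    dt = np.median(np.diff(t))
    n_w = max(int(round(window_seconds / dt)) + 1, 2)
    if n_w > t.size:
        raise ValueError("fit window holds fewer than the available samples")
    starts, slopes, r2 = _rolling_slopes(t, T, n_w)
    i = int(np.argmax(slopes))
    return SlopeEstimate(
        dTdt_max=float(slopes[i]),
        window=(int(starts[i]), int(starts[i]) + n_w),
        r_squared=float(r2[i]),
    )


def sar_from_curve(curve: HeatingCurve, slope: SlopeEstimate) -> float:
    """Calorimetric SAR ``c * rho * (dT/dt)_max / m_Fe`` in W/kg."""
    return curve.c * curve.rho * slope.dTdt_max / curve.m_Fe


def compare_model_measurement(
    model: pd.DataFrame, measured: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Percent deviation of model SAR from measured SAR, point by point.

    Both tables must carry the key columns (H_kA_per_m, f_kHz, mode) and a
    SAR_W_per_g column.  Returns the merged table with a
    ``deviation_percent`` column ((model - measured)/measured * 100) and a
    summary dict with ``max_abs_deviation_percent`` and
    ``mean_deviation_percent``.
    """
    for name, df in (("model", model), ("measured", measured)):
        missing = [k for k in MERGE_KEYS + ["SAR_W_per_g"] if k not in df.columns]
        if missing:
            raise ValueError(f"{name} table is missing columns: {missing}")
    merged = model.merge(
        measured, on=MERGE_KEYS, how="outer", suffixes=("_model", "_measured"),
        indicator=True,
    )
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        keys = unmatched[MERGE_KEYS].to_dict("records")
        raise ValueError(f"tables do not share these field points: {keys}")
    merged = merged.drop(columns="_merge")
    merged["deviation_percent"] = (
        (merged["SAR_W_per_g_model"] - merged["SAR_W_per_g_measured"])
        / merged["SAR_W_per_g_measured"] * 100.0
    )
    summary = {
        "max_abs_deviation_percent": float(merged["deviation_percent"].abs().max()),
        "mean_deviation_percent": float(merged["deviation_percent"].mean()),
        "n_points": int(len(merged)),
    }
    return merged, summary
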