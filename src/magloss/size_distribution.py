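"""Particle-size statistics: from measured diameters to group volume fractions.

TEM sizing yields a *number-weighted* sample of equivalent diameters.  The
power calculation, however, needs the *volume* carried by each size class:
a particle of diameter d contributes proportionally to d^3.  This module

1. converts number-weighted observations to volume weights,
2. fits log-normal distributions (weighted maximum likelihood on log
   diameters, closed form — no optimizer),
3. builds the discrete size-group grid and distributes the total volume
   fraction ``phi`` over it:

       phi_d_i = V_actual_i * phi / sum_j V_actual_j

   so the group fractions always sum back to phi exactly, and
4. recovers ``phi`` itself from fluid magnetometry as
   ``phi = M_s_fluid / M_d``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizeObservations",
    "LogNormalParams",
    "LogNormalFit",
    "GroupVector",
    "total_volume_fraction",
    "number_to_volume_weights",
    "fit_lognormal",
    "fit_lognormal_both",
    "make_group_grid",
    "group_volume_fractions",
    "bin_to_grid",
]


@dataclass
class SizeObservations:
    """Equivalent diameters (m) with optional per-diameter counts."""

    diameters: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.size == 0:
            raise ValueError("at least one diameter is required")
        if np.any(self.diameters <= 0):
            raise ValueError("all diameters must be positive")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.diameters.shape:
                raise ValueError("counts must match diameters in shape")
            if np.any(self.counts < 0) or self.counts.sum() <= 0:
                raise ValueError("counts must be non-negative with positive sum")

    @property
    def effective_counts(self) -> np.ndarray:
        if self.counts is None:
            return np.ones_like(self.diameters)
        return self.counts


@dataclass
class LogNormalParams:
    """One weighted log-normal fit: log-space and arithmetic moments."""

    median: float  # m, exp(mu)
    shape: float  # dimensionless sigma of log(d)
    mean: float  # m, arithmetic
    std: float  # m, arithmetic


@dataclass
class LogNormalFit:
    """Number- and volume-weighted log-normal fits of the same sample.

    d_N/sigma_N and d_V/sigma_V are arithmetic means and standard
    deviations under the two weightings; d_V >= d_N for any nondegenerate
    sample because volume weighting favours large particles.
    """

    d_N: float
    sigma_N: float
    d_V: float
    sigma_V: float
    number: LogNormalParams | None = None
    volume: LogNormalParams | None = None


@dataclass
class GroupVector:
    """Size-group grid with per-group volume fractions of the suspension."""

    d_grid: np.ndarray  # m, strictly increasing
    phi_d: np.ndarray  # dimensionless, sums to total phi

    def __post_init__(self) -> None:
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.phi_d = np.asarray(self.phi_d, dtype=float)
        if self.d_grid.shape != self.phi_d.shape:
            raise ValueError("d_grid and phi_d must have the same shape")
        if np.any(np.diff(self.d_grid) <= 0):
            raise ValueError("d_grid must be strictly increasing")
        if np.any(self.phi_d < 0):
            raise ValueError("phi_d must be non-negative")

    @property
    def phi_total(self) -> float:
        return float(self.phi_d.sum())


def total_volume_fraction(M_s_fluid: float, M_d: float) -> float:
    """Volume fraction of magnetic material from fluid magnetometry.

    The fluid's saturation magnetization is the bulk value diluted by the
    volume loading, so ``phi = M_s_fluid / M_d``.
    """
    if M_d <= 0:
        raise ValueError("bulk saturation magnetization must be positive")
    if M_s_fluid < 0:
        raise ValueError("fluid saturation magnetization must be non-negative")
    if M_s_fluid >= M_d:
        raise ValueError(
            "fluid magnetization must be below the bulk value: "
            f"{M_s_fluid} >= {M_d} is non-physical"
        )
    return M_s_fluid / M_d


def number_to_volume_weights(diameters, counts) -> np.ndarray:
    """Normalized volume weights ``w_i ∝ count_i * d_i^3``."""
    d = np.asarray(diameters, dtype=float)
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    w = c * d**3
    total = w.sum()
    if total <= 0:
        raise ValueError("all counts are zero: no particles to weight")
    return w / total


def _weighted_lognormal_mle(d: np.ndarray, w: np.ndarray) -> LogNormalParams:
    w = w / w.sum()
    log_d = np.log(d)
    mu = float(np.sum(w * log_d))
    sigma = float(math.sqrt(np.sum(w * (log_d - mu) ** 2)))
    mean = math.exp(mu + sigma**2 / 2.0)
    std = mean * math.sqrt(math.expm1(sigma**2))
    return LogNormalParams(median=math.exp(mu), shape=sigma, mean=mean, std=std)


def fit_lognormal(
    observations: SizeObservations, weighting: str = "number"
) -> LogNormalParams:
    """Weighted maximum-likelihood log-normal fit of a diameter sample.

    ``weighting="number"`` uses the raw counts; ``"volume"`` weights each
    particle by its volume (d^3) first.  The MLE on log diameters is closed
    form; arithmetic mean and std follow from the standard moment relations
    mean = exp(mu + sigma^2/2), std = mean*sqrt(exp(sigma^2)-1).
    """
    d = observations.diameters
    c = observations.effective_counts
    if c.sum() < 10:
        raise ValueError("at least 10 observations are required for a stable fit")
    if weighting == "number":
        w = c.astype(float)
    elif weighting == "volume":
        w = number_to_volume_weights(d, c)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return _weighted_lognormal_mle(d, w)


def fit_lognormal_both(observations: SizeObservations) -> LogNormalFit:
    """Number- and volume-weighted fits of the same sample in one record."""
    num = fit_lognormal(observations, "number")
    vol = fit_lognormal(observations, "volume")
    return LogNormalFit(
        d_N=num.mean, sigma_N=num.std, d_V=vol.mean, sigma_V=vol.std,
        number=num, volume=vol,
    )


def make_group_grid(d_min: float, d_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic diameter grid from d_min to d_max."""
    if step <= 0:
        raise ValueError("step must be positive")
    if d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    n = int(math.floor((d_max - d_min) / step + 1.0 + 1e-9))
    if n < 1:
        raise ValueError("grid is empty")
    return d_min + step * np.arange(n)


def group_volume_fractions(d_grid, V_actual, phi: float) -> GroupVector:
    """Distribute the total volume fraction over size groups.

    ``phi_d_i = V_actual_i * phi / sum(V_actual)`` — the relative group
    volumes are only needed up to an overall scale, and the output sums
    to phi by construction.
    """
    V = np.asarray(V_actual, dtype=float)
    if np.any(V < 0):
        raise ValueError("relative group volumes must be non-negative")
    total = V.sum()
    if total <= 0:
        raise ValueError("all relative group volumes are zero")
    if not 0 < phi < 1:
        raise ValueError(f"total volume fraction must be in (0, 1), got {phi}")
    return GroupVector(d_grid=np.asarray(d_grid, dtype=float), phi_d=V * (phi / total))


def bin_to_grid(observations: SizeObservations, d_grid) -> np.ndarray:
    """Relative per-group volumes from raw diameters by nearest-grid binning.

    Each observed diameter is assigned to the nearest grid point (ties go to
    the lower bin) and contributes count * d^3 to that group's volume.
    """
    grid = np.asarray(d_grid, dtype=float)
    d = observations.diameters
    c = observations.effective_counts
    # argmin returns the first (lower) index on exact ties
    idx = np.abs(d[:, None] - grid[None, :]).argmin(axis=1)
    V = np.zeros(grid.size)
    np.add.at(V, idx, c * d**3)
    return V
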