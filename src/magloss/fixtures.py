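"""Synthetic data generators with known ground truth.

No public dataset accompanies this kind of loss characterization — particle
sizing lives in TEM images and SAR measurements in lab notebooks — so every
pipeline stage is exercised on synthetic inputs whose true parameters are
known exactly:

* ``sample_diameters`` — i.i.d. log-normal "TEM" diameter samples;
* ``surrogate_group_vector`` — a smooth unimodal volume-fraction vector on
  the size-group grid pinned to a quoted anchor value and total;
* ``generate_heating_curve`` — a saturating-exponential calorimetric trace
  with Gaussian probe noise whose analytic initial slope encodes a known
  SAR.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import lognorm

from .calorimetry import HeatingCurve
from .size_distribution import GroupVector, SizeObservations

__all__ = [
    "FixtureConfig",
    "sample_diameters",
    "surrogate_group_vector",
    "generate_heating_curve",
]


@dataclass
class FixtureConfig:
    """Knobs of the synthetic generators.

    Defaults mirror the characterized fluid: ~500 particles sized by TEM
    with a log-normal distribution around 9 nm (shape 0.25), a fiber-optic
    probe with ~0.02 K noise sampling at 50 Hz for a minute.
    """

    seed: int = 0
    n_particles: int = 500
    lognormal_median: float = 9e-9  # m
    lognormal_shape: float = 0.25
    noise_sigma_K: float = 0.02
    curve_duration_s: float = 60.0
    sample_rate_Hz: float = 50.0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be at least 1")
        for name in ("lognormal_median", "lognormal_shape",
                     "curve_duration_s", "sample_rate_Hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma_K < 0:
            raise ValueError("noise_sigma_K must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_diameters(config: FixtureConfig) -> SizeObservations:
    """I.i.d. log-normal equivalent diameters emulating a TEM size sample."""
    rng = config.rng()
    log_d = math.log(config.lognormal_median) + config.lognormal_shape * (
        rng.standard_normal(config.n_particles)
    )
    return SizeObservations(diameters=np.exp(log_d))


def surrogate_group_vector(
    d_grid,
    anchor: tuple[float, float],
    phi_total: float,
    median: float = 8.5e-9,
    shape: float = 0.28,
) -> GroupVector:
    """Synthetic per-group volume-fraction vector pinned to an anchor.

    Builds a discretized log-normal volume distribution on the grid, then
    rescales so the anchor group carries exactly ``anchor[1]`` and the whole
    vector sums exactly to ``phi_total``.  This is a synthetic surrogate for
    an empirically measured group-volume vector: it honours the two numbers
    that are known (one group's fraction and the total) and interpolates a
    plausible unimodal shape between them.
    """
    grid = np.asarray(d_grid, dtype=float)
    d_anchor, phi_anchor = anchor
    matches = np.isclose(grid, d_anchor, rtol=1e-9, atol=0.0)
    if not matches.any():
        raise ValueError(f"anchor diameter {d_anchor} is not on the group grid")
    i_anchor = int(np.argmax(matches))
    if not 0 <= phi_anchor <= phi_total:
        raise ValueError(
            f"anchor fraction {phi_anchor} infeasible for total {phi_total}"
        )
    if grid.size == 1:
        if not math.isclose(phi_anchor, phi_total, rel_tol=1e-12):
            raise ValueError("single-group grid requires anchor == total")
        return GroupVector(d_grid=grid, phi_d=np.array([phi_total]))

    p = lognorm.pdf(grid, s=shape, scale=median)
    others = np.arange(grid.size) != i_anchor
    rest = p[others].sum()
    if rest <= 0:
        raise ValueError("distribution mass vanishes away from the anchor")
    phi_d = np.empty(grid.size)
    phi_d[i_anchor] = phi_anchor
    phi_d[others] = p[others] * ((phi_total - phi_anchor) / rest)
    return GroupVector(d_grid=grid, phi_d=phi_d)


def generate_heating_curve(
    sar_true: float,
    c: float,
    rho: float,
    m_Fe: float,
    tau_c: float,
    config: FixtureConfig,
    T0: float = 25.0,
) -> HeatingCurve:
    """Noisy saturating heating curve with a known ground-truth SAR.

    The deterministic part is ``T(t) = T0 + dT0 * tau_c * (1 - exp(-t/tau_c))``
    with initial slope ``dT0 = sar_true * m_Fe / (c * rho)`` — exactly the
    quantity the calorimetric estimator must recover — saturating on the
    heat-loss time scale ``tau_c``.  Gaussian noise of ``noise_sigma_K`` is
    added to every sample.
    """
    if sar_true < 0:
        raise ValueError("sar_true must be non-negative")
    if min(c, rho, m_Fe, tau_c) <= 0:
        raise ValueError("c, rho, m_Fe and tau_c must be positive")
    n = int(round(config.curve_duration_s * config.sample_rate_Hz)) + 1
    t = np.arange(n) / config.sample_rate_Hz
    slope0 = sar_true * m_Fe / (c * rho)
    T = T0 + slope0 * tau_c * (1.0 - np.exp(-t / tau_c))
    if config.noise_sigma_K > 0:
        T = T + config.rng().normal(0.0, config.noise_sigma_K, size=n)
    return HeatingCurve(t=t, T=T, c=c, rho=rho, m_Fe=m_Fe)
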