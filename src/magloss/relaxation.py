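"""Magnetic relaxation times of superparamagnetic nanoparticles.

A single-domain nanoparticle suspended in a carrier liquid relaxes its
magnetization by two parallel channels:

* **Néel relaxation** — the moment flips internally over the anisotropy
  energy barrier ``K_a * V_p``::

      tau_N = tau0 * exp(K_a * V_p / (k_B * T))

* **Brownian relaxation** — the whole particle (core plus surfactant
  shell) rotates in the liquid against viscous drag::

      tau_B = 3 * V_h * eta / (k_B * T)

The channels act in parallel, so the effective time is the harmonic
combination ``tau = (1/tau_N + 1/tau_B)^-1`` and the faster mechanism
dominates.  Néel relaxation wins for small cores (the exponential is mild),
Brownian for large ones; the crossover diameter where ``tau_N == tau_B``
separates the two regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .constants import K_B

__all__ = [
    "ParticleGroup",
    "OperatingConditions",
    "neel_time",
    "brownian_time",
    "effective_time",
    "crossover_diameter",
    "DEFAULT_TAU0",
    "DEFAULT_DELTA",
    "DEFAULT_K_A",
]

#: Attempt time of the Néel process, s.
DEFAULT_TAU0 = 1e-9
#: Surfactant (fatty-acid) layer thickness, m.
DEFAULT_DELTA = 1e-9
#: Effective anisotropy constant of maghemite nanoparticles, J/m^3.
#: Not directly measurable for a given sample without magnetometry; this is
#: the standard literature value and is exposed as a calibration knob.
DEFAULT_K_A = 4.7e4

# exp() overflows IEEE doubles near exponent 709
_EXP_OVERFLOW = 700.0


@dataclass
class ParticleGroup:
    """One size class of magnetic cores in the suspension.

    Parameters
    ----------
    d_core : float
        Magnetic core diameter, m.
    delta : float
        Surfactant layer thickness, m (adds to the hydrodynamic radius).
    K_a : float
        Effective anisotropy constant, J/m^3.
    tau0 : float
        Néel attempt time, s.
    phi_d : float
        Volume fraction of this size class in the suspension.
    """

    d_core: float
    delta: float = DEFAULT_DELTA
    K_a: float = DEFAULT_K_A
    tau0: float = DEFAULT_TAU0
    phi_d: float = 0.0

    def __post_init__(self) -> None:
        if self.d_core <= 0:
            raise ValueError(f"d_core must be positive, got {self.d_core}")
        if self.delta < 0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if self.K_a < 0:
            raise ValueError(f"K_a must be non-negative, got {self.K_a}")
        if self.tau0 <= 0:
            raise ValueError(f"tau0 must be positive, got {self.tau0}")
        if not 0.0 <= self.phi_d <= 1.0:
            raise ValueError(f"phi_d must be in [0, 1], got {self.phi_d}")

    @property
    def V_p(self) -> float:
        """Core volume of a spherical particle, m^3."""
        return math.pi / 6.0 * self.d_core**3

    @property
    def V_h(self) -> float:
        """Hydrodynamic volume including the surfactant shell, m^3."""
        return math.pi / 6.0 * (self.d_core + 2.0 * self.delta) ** 3


@dataclass
class OperatingConditions:
    """Thermodynamic state of the carrier: temperature and viscosity at T."""

    T: float  # K
    eta: float  # Pa*s

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"absolute temperature must be positive, got {self.T}")
        if self.eta <= 0:
            raise ValueError(f"viscosity must be positive, got {self.eta}")


def neel_time(group: ParticleGroup, cond: OperatingConditions) -> float:
    """Néel relaxation time ``tau0 * exp(K_a V_p / k_B T)`` in seconds.

    Saturates to ``+inf`` when the exponent would overflow (very large or
    strongly anisotropic cores are effectively thermally blocked), so the
    effective time degrades gracefully to the Brownian channel.
    """
    exponent = group.K_a * group.V_p / (K_B * cond.T)
    if exponent > _EXP_OVERFLOW:
        return math.inf
    return group.tau0 * math.exp(exponent)


def brownian_time(group: ParticleGroup, cond: OperatingConditions) -> float:
    """Brownian rotational relaxation time ``3 V_h eta / (k_B T)`` in seconds."""
    return 3.0 * group.V_h * cond.eta / (K_B * cond.T)


def effective_time(tau_N: float, tau_B: float) -> float:
    """Harmonic combination of the two parallel relaxation channels.

    Either input may be ``+inf`` (channel closed); both infinite means the
    system does not relax at all and raises ``ValueError``.
    """
    if tau_N <= 0 or tau_B <= 0:
        raise ValueError("relaxation times must be positive")
    if math.isinf(tau_N) and math.isinf(tau_B):
        raise ValueError("both relaxation channels blocked: system does not relax")
    if math.isinf(tau_N):
        return tau_B
    if math.isinf(tau_B):
        return tau_N
    return 1.0 / (1.0 / tau_N + 1.0 / tau_B)


def crossover_diameter(
    K_a: float,
    tau0: float,
    delta: float,
    cond: OperatingConditions,
    d_min: float = 1e-9,
    d_max: float = 100e-9,
) -> float:
    """Core diameter at which the Néel and Brownian times are equal, m.

    Below the crossover the Néel mechanism prevails, above it the Brownian
    one.  Solved as a bracketed root of ``log(tau_N) - log(tau_B)`` on
    ``[d_min, d_max]`` (log space keeps the residual finite where the Néel
    exponential would overflow a double).

    Raises
    ------
    ValueError
        If the parameters are non-positive or the bracket contains no sign
        change ("no crossover in range").
    """
    if K_a <= 0 or tau0 <= 0 or delta < 0:
        raise ValueError("K_a and tau0 must be positive, delta non-negative")

    kT = K_B * cond.T

    def log_ratio(d: float) -> float:
        log_tau_N = math.log(tau0) + K_a * (math.pi / 6.0) * d**3 / kT
        V_h = math.pi / 6.0 * (d + 2.0 * delta) ** 3
        log_tau_B = math.log(3.0 * V_h * cond.eta / kT)
        return log_tau_N - log_tau_B

    f_lo, f_hi = log_ratio(d_min), log_ratio(d_max)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no crossover in range [{d_min:.3g}, {d_max:.3g}] m: "
            "tau_N/tau_B does not change sign"
        )
    # xtol well below any physical diameter so rtol controls convergence
    return brentq(log_ratio, d_min, d_max, rtol=1e-12, xtol=1e-20)
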