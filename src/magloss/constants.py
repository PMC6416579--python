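"""Physical constants used throughout the model (SI units)."""

from dataclasses import dataclass
import math


@dataclass(frozen=True)
class PhysicalConstants:
    """Boltzmann constant and vacuum permeability.

    k_B is fixed at 1.38e-23 J/K (the rounded value conventional in the
    magnetic-fluid loss literature) rather than the CODATA value, so that
    results are comparable with published loss calculations.
    """

    k_B: float = 1.38e-23  # J/K
    mu0: float = 4 * math.pi * 1e-7  # T*m/A


CONSTANTS = PhysicalConstants()
K_B = CONSTANTS.k_B
MU0 = CONSTANTS.mu0

CELSIUS_ZERO = 273.15  # K


def celsius_to_kelvin(T_C: float) -> float:
    return T_C + CELSIUS_ZERO
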