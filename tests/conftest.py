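import numpy as np
import pytest

from magloss import (
    FixtureConfig,
    MaterialSpec,
    OperatingConditions,
    ParticleGroup,
    make_group_grid,
    surrogate_group_vector,
)

#: characterized-fluid parameters used across the suite
M_D = 4.0e5  # A/m, bulk saturation magnetization of maghemite
RHO_M = 4860.0  # kg/m^3
PHI_TOTAL = 0.1057
ANCHOR = (7.5e-9, 0.01611)


@pytest.fixture
def conditions():
    """Room-temperature mineral-oil carrier (surrogate viscosity)."""
    return OperatingConditions(T=298.15, eta=0.0633)


@pytest.fixture
def material():
    return MaterialSpec(M_d=M_D, rho_m=RHO_M, phi=PHI_TOTAL)


@pytest.fixture
def twelve_groups():
    """The twelve 3.5-14.5 nm size classes with the surrogate fractions."""
    grid = make_group_grid(3.5e-9, 14.5e-9, 1e-9)
    vec = surrogate_group_vector(grid, anchor=ANCHOR, phi_total=PHI_TOTAL)
    return [
        ParticleGroup(d_core=float(d), phi_d=float(p))
        for d, p in zip(vec.d_grid, vec.phi_d)
    ]


@pytest.fixture
def fixture_config():
    return FixtureConfig(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
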