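"""Run configuration: TOML parsing, validation, and unit handling.

All physics inside the package is SI (m, s, K, A/m, Pa*s, J/m^3).  Config
files and CLI boundaries use the field's display units (nm, kA/m, kHz, W/g,
mPa*s); quantities in config files are written as strings like ``"4.3 kA/m"``
and converted exactly once, here.
"""

from __future__ import annotations

import logging
import tomllib
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .material_properties import PropertyPoints
from .relaxation import DEFAULT_DELTA, DEFAULT_K_A, DEFAULT_TAU0

__all__ = ["parse_quantity", "format_quantity", "RunConfig", "load_config"]

log = logging.getLogger("magloss")

# multiplicative factors to SI for each recognised unit string
_UNIT_FACTORS: dict[str, float] = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
    # magnetic field
    "A/m": 1.0, "kA/m": 1e3,
    # frequency
    "Hz": 1.0, "kHz": 1e3, "MHz": 1e6,
    # time
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9,
    # viscosity
    "Pa.s": 1.0, "Pa*s": 1.0, "mPa.s": 1e-3, "mPa*s": 1e-3,
    # density / mass concentration
    "kg/m^3": 1.0, "g/cm^3": 1e3,
    # energy density (anisotropy)
    "J/m^3": 1.0, "kJ/m^3": 1e3,
    # specific heat
    "J/(kg.K)": 1.0, "kJ/(kg.K)": 1e3,
    # power per mass
    "W/kg": 1.0, "W/g": 1e3,
}


def parse_quantity(text: str | float | int) -> float:
    """Parse ``"4.3 kA/m"`` (or a bare number, taken as SI) to an SI float."""
    if isinstance(text, (int, float)):
        return float(text)
    parts = text.strip().split()
    if len(parts) == 1:
        try:
            return float(parts[0])
        except ValueError:
            raise ValueError(f"cannot parse quantity {text!r}") from None
    if len(parts) != 2:
        raise ValueError(f"cannot parse quantity {text!r}: expected 'value unit'")
    value_s, unit = parts
    try:
        value = float(value_s)
    except ValueError:
        raise ValueError(f"cannot parse number in quantity {text!r}") from None
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r} in quantity {text!r}")
    return value * _UNIT_FACTORS[unit]


def format_quantity(value_si: float, unit: str, digits: int = 10) -> str:
    """Render an SI value in a display unit, e.g. 4300.0, 'kA/m' -> '4.3'."""
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r}")
    return f"{value_si / _UNIT_FACTORS[unit]:.{digits}g}"


class MaterialBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    M_d: str | float
    rho_m: str | float = 4860.0
    phi: float | None = None
    M_s_fluid: str | float | None = None

    @model_validator(mode="after")
    def _exactly_one_loading(self):
        if (self.phi is None) == (self.M_s_fluid is None):
            raise ValueError(
                "material block: give exactly one of 'phi' or 'M_s_fluid'"
            )
        return self


class GridBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_min: str | float
    d_max: str | float
    step: str | float


class DistributionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    anchor_d: str | float
    anchor_phi_percent: float


class GroupsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid: GridBlock | None = None
    distribution: DistributionBlock | None = None
    d: list[str | float] | None = None
    phi_d_percent: list[float] | None = None

    @model_validator(mode="after")
    def _exactly_one_source(self):
        grid_given = self.grid is not None and self.distribution is not None
        explicit = self.d is not None and self.phi_d_percent is not None
        if grid_given == explicit:
            raise ValueError(
                "groups block: give either 'grid'+'distribution' or "
                "explicit 'd'+'phi_d_percent', not both or neither"
            )
        if explicit and len(self.d) != len(self.phi_d_percent):
            raise ValueError("groups block: 'd' and 'phi_d_percent' lengths differ")
        return self


class CarrierBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    viscosity_T_C: list[float]
    viscosity: list[str | float]
    density_T_C: list[float] | None = None
    density: list[str | float] | None = None


class FieldBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    H: list[str | float]
    f: list[str | float]
    mode: Literal["alternating", "rotating"] = "alternating"


class OptionsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sar_convention: Literal["per-magnetic-mass", "literal"] = "per-magnetic-mass"
    tau0: str | float = DEFAULT_TAU0
    K_a: str | float = DEFAULT_K_A
    delta: str | float = DEFAULT_DELTA
    temperature_C: float = 25.0


class RunConfig(BaseModel):
    """Validated pipeline configuration with all defaults resolved."""

    model_config = ConfigDict(extra="forbid")
    material: MaterialBlock
    groups: GroupsBlock
    carrier: CarrierBlock
    field: FieldBlock = Field(alias="field")
    options: OptionsBlock = OptionsBlock()

    # --- resolved SI accessors -------------------------------------------
    @property
    def M_d(self) -> float:
        return parse_quantity(self.material.M_d)

    @property
    def rho_m(self) -> float:
        return parse_quantity(self.material.rho_m)

    @property
    def phi(self) -> float:
        if self.material.phi is not None:
            return self.material.phi
        from .size_distribution import total_volume_fraction

        return total_volume_fraction(parse_quantity(self.material.M_s_fluid), self.M_d)

    @property
    def amplitudes(self) -> list[float]:
        return [parse_quantity(h) for h in self.field.H]

    @property
    def frequencies(self) -> list[float]:
        return [parse_quantity(f) for f in self.field.f]

    @property
    def viscosity_points(self) -> PropertyPoints:
        return PropertyPoints(
            temperatures=np.asarray(self.carrier.viscosity_T_C),
            values=np.asarray([parse_quantity(v) for v in self.carrier.viscosity]),
        )

    @property
    def density_points(self) -> PropertyPoints | None:
        if self.carrier.density_T_C is None or self.carrier.density is None:
            return None
        return PropertyPoints(
            temperatures=np.asarray(self.carrier.density_T_C),
            values=np.asarray([parse_quantity(v) for v in self.carrier.density]),
        )

    @property
    def tau0(self) -> float:
        return parse_quantity(self.options.tau0)

    @property
    def K_a(self) -> float:
        return parse_quantity(self.options.K_a)

    @property
    def delta(self) -> float:
        return parse_quantity(self.options.delta)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration, logging resolved defaults."""
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig.model_validate(raw)
    log.info(
        "resolved parameters: phi=%.6g, M_d=%.6g A/m, rho_m=%.6g kg/m^3, "
        "K_a=%.6g J/m^3, tau0=%.3g s, delta=%.3g m, T=%.4g degC, "
        "sar_convention=%s",
        cfg.phi, cfg.M_d, cfg.rho_m, cfg.K_a, cfg.tau0, cfg.delta,
        cfg.options.temperature_C, cfg.options.sar_convention,
    )
    return cfg
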