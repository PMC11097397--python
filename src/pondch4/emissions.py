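"""Emission-factor tiers for methane flux from agricultural ponds.

Three levels of inventory method are implemented, mirroring IPCC practice for
flooded lands:

* **tier 1** — a single fixed emission factor applied everywhere,
* **tier 2** — one constant factor per Köppen-style climate zone,
* **tier 3** — a Boltzmann–Arrhenius temperature response,

  ``M(T) = M15 * exp[(E_M / k_B) * (1/T15 - 1/T)]``

  where ``M15`` is the annual flux standardised to 15 °C
  (t CH4 ha⁻¹ yr⁻¹), ``E_M`` the apparent activation energy of
  methanogenesis (eV), ``k_B`` the Boltzmann constant (eV K⁻¹) and ``T`` the
  pond's mean air temperature in Kelvin (air temperature is used as the pond
  temperature proxy).

All fluxes are stored in t CH4 ha⁻¹ yr⁻¹; converting to kg is an I/O concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_EV",
    "T_REF_KELVIN",
    "ArrheniusParams",
    "Tier1Params",
    "Tier2Params",
    "tier1_flux",
    "tier2_flux",
    "tier3_flux",
    "flux_ratio",
    "monthly_emission",
]

#: Boltzmann constant in eV K^-1.
BOLTZMANN_EV = 8.617e-5

#: Standardisation temperature of the calibrated flux (15 degC in Kelvin).
T_REF_KELVIN = 288.15

# Plausible range for a mean monthly air temperature anywhere on Earth.
_TEMP_MIN_C = -90.0
_TEMP_MAX_C = 60.0


@dataclass(frozen=True)
class ArrheniusParams:
    """Calibrated tier-3 (Boltzmann–Arrhenius) parameters with 95% CIs.

    Defaults are the literature calibration for small waterbodies:
    M15 = 0.204 (95% CI 0.083–0.521) t CH4 ha⁻¹ yr⁻¹ and
    E_M = 0.43 (95% CI 0.21–0.64) eV.
    """

    m15: float = 0.204
    m15_ci: tuple[float, float] = (0.083, 0.521)
    e_m: float = 0.43
    e_m_ci: tuple[float, float] = (0.21, 0.64)
    t_ref: float = T_REF_KELVIN
    k_b: float = BOLTZMANN_EV

    def __post_init__(self) -> None:
        if not self.m15 > 0:
            raise ValueError(f"m15 must be positive, got {self.m15}")
        if not (self.m15_ci[0] <= self.m15 <= self.m15_ci[1]):
            raise ValueError(f"m15={self.m15} outside its CI {self.m15_ci}")
        if not (self.e_m_ci[0] <= self.e_m <= self.e_m_ci[1]):
            raise ValueError(f"e_m={self.e_m} outside its CI {self.e_m_ci}")
        if not self.t_ref > 0:
            raise ValueError("t_ref must be positive (Kelvin)")


@dataclass(frozen=True)
class Tier1Params:
    """Fixed tier-1 emission factor, t CH4 ha⁻¹ yr⁻¹ (default 0.183)."""

    ef: float = 0.183
    ef_ci: tuple[float, float] = (0.118, 0.228)


#: Tier-2 climate-zone emission factors, t CH4 ha^-1 yr^-1.
DEFAULT_ZONE_EF: dict[str, float] = {
    "subtropical": 0.381,
    "temperate-cool": 0.152,
    "temperate-warm": 0.238,
    "tropical-dry": 0.581,
    "tropical-wet": 0.697,
}


@dataclass(frozen=True)
class Tier2Params:
    """Per-climate-zone tier-2 emission factors."""

    zone_ef: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_EF)
    )

    def __post_init__(self) -> None:
        bad = {z: v for z, v in self.zone_ef.items() if not v > 0}
        if bad:
            raise ValueError(f"zone emission factors must be positive: {bad}")


def tier3_flux(temp_c, params: ArrheniusParams | None = None):
    """Annual methane flux (t CH4 ha⁻¹ yr⁻¹) at mean air temperature `temp_c`.

    Evaluates the Boltzmann–Arrhenius response; equals ``params.m15`` exactly
    at 15 °C and increases monotonically with temperature. Accepts scalars or
    arrays.
    """
    if params is None:
        params = ArrheniusParams()
    t = np.asarray(temp_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    if np.any(t <= _TEMP_MIN_C) or np.any(t >= _TEMP_MAX_C):
        raise ValueError(
            f"temperature outside plausible range "
            f"({_TEMP_MIN_C}, {_TEMP_MAX_C}) degC"
        )
    t_kelvin = t + 273.15
    exponent = (params.e_m / params.k_b) * (1.0 / params.t_ref - 1.0 / t_kelvin)
    flux = params.m15 * np.exp(exponent)
    return flux if flux.ndim else float(flux)


def tier1_flux(params: Tier1Params | None = None) -> float:
    """Fixed tier-1 annual flux, independent of temperature and climate."""
    if params is None:
        params = Tier1Params()
    return params.ef


def tier2_flux(zone: str, params: Tier2Params | None = None) -> float:
    """Tier-2 annual flux for one climate zone."""
    if params is None:
        params = Tier2Params()
    try:
        return params.zone_ef[zone]
    except KeyError:
        raise KeyError(
            f"unknown climate zone {zone!r}; known zones: "
            f"{sorted(params.zone_ef)}"
        ) from None


def monthly_emission(annual_flux, water_area):
    """Methane emitted in one month (t CH4) from `water_area` hectares.

    The annual areal rate is split evenly over twelve months:
    ``annual_flux * water_area / 12``.
    """
    flux = np.asarray(annual_flux, dtype=float)
    area = np.asarray(water_area, dtype=float)
    if np.any(flux < 0):
        raise ValueError("annual_flux must be non-negative")
    if np.any(area < 0):
        raise ValueError("water_area must be non-negative")
    out = flux * area / 12.0
    return out if out.ndim else float(out)


def flux_ratio(
    temp_c: float,
    params3: ArrheniusParams | None = None,
    params1: Tier1Params | None = None,
    round_fluxes: bool = False,
) -> float:
    """Ratio of the tier-3 flux at `temp_c` to the fixed tier-1 factor.

    With ``round_fluxes=True`` both fluxes are rounded to two decimals before
    dividing, matching how the ratio is quoted from printed values.
    """
    if params1 is None:
        params1 = Tier1Params()
    f3 = tier3_flux(temp_c, params3)
    f1 = tier1_flux(params1)
    if round_fluxes:
        f3, f1 = round(f3, 2), round(f1, 2)
    if f1 == 0:
        raise ZeroDivisionError("tier-1 emission factor is zero")
    return f3 / f1
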