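"""Declarative run configuration (YAML) with strict validation.

A single file configures every stage — generators, training protocol,
emission-factor parameters, uncertainty settings — with the package defaults
filled in for anything omitted. Unknown keys are rejected so typos fail loudly
rather than silently reverting to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict

from pondch4.emissions import (
    DEFAULT_ZONE_EF,
    ArrheniusParams,
    Tier1Params,
    Tier2Params,
)
from pondch4.surface import SearchConfig
from pondch4.synthetic import ClimateConfig, LandscapeConfig, SurfaceTruth
from pondch4.uncertainty import DEFAULT_SURFACE_ERROR_CV

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LandscapeSection(_Strict):
    n_ponds: int = 2000
    years: tuple[int, int] = (1990, 2022)
    irregular_fraction: float = 0.05
    size_sigma: float = 1.0

    def to_dataclass(self, seed: int) -> LandscapeConfig:
        return LandscapeConfig(
            n_ponds=self.n_ponds,
            years=self.years,
            irregular_fraction=self.irregular_fraction,
            size_sigma=self.size_sigma,
            seed=seed,
        )


class ClimateSection(_Strict):
    temp_noise_sd: float = 1.0
    rain_shape: float = 2.0
    rain_scale_mm: float = 30.0
    anomaly_amplitude: float = 0.3
    anomaly_period_years: float = 6.0

    def to_dataclass(self, seed: int) -> ClimateConfig:
        return ClimateConfig(
            temp_noise_sd=self.temp_noise_sd,
            rain_shape=self.rain_shape,
            rain_scale_mm=self.rain_scale_mm,
            anomaly_amplitude=self.anomaly_amplitude,
            anomaly_period_years=self.anomaly_period_years,
            seed=seed,
        )


class TruthSection(_Strict):
    intercept: float = 0.45
    beta_rain: float = 0.7
    beta_temp: float = -0.15
    pond_effect_sd: float = 0.6
    noise_sd: float = 0.75

    def to_dataclass(self) -> SurfaceTruth:
        return SurfaceTruth(**self.model_dump())


class SearchSection(_Strict):
    n_random: int = 15
    n_guided: int = 30
    ensemble_size: int = 10
    learning_rate_range: tuple[float, float] = (0.1, 0.5)
    n_estimators_range: tuple[int, int] = (10, 700)
    max_depth_range: tuple[int, int] = (1, 10)
    val_fraction: float = 0.1
    max_area_cap: float = 2.0
    min_examples: int = 100
    max_examples: int | None = 20000

    def to_dataclass(self) -> SearchConfig:
        d = self.model_dump()
        d.pop("max_examples")
        return SearchConfig(**d)


class EmissionSection(_Strict):
    m15: float = 0.204
    m15_ci: tuple[float, float] = (0.083, 0.521)
    e_m: float = 0.43
    e_m_ci: tuple[float, float] = (0.21, 0.64)
    tier1_ef: float = 0.183
    tier1_ci: tuple[float, float] = (0.118, 0.228)
    zone_ef: dict[str, float] = dict(DEFAULT_ZONE_EF)

    def params(self, tier: str):
        if tier == "tier3":
            return ArrheniusParams(
                m15=self.m15, m15_ci=self.m15_ci,
                e_m=self.e_m, e_m_ci=self.e_m_ci,
            )
        if tier == "tier1":
            return Tier1Params(ef=self.tier1_ef, ef_ci=self.tier1_ci)
        if tier == "tier2":
            return Tier2Params(zone_ef=self.zone_ef)
        raise ValueError(f"unknown tier {tier!r}")


class UncertaintySection(_Strict):
    n_draws: int = 1000
    surface_error_cv: float = DEFAULT_SURFACE_ERROR_CV


class FilterSection(_Strict):
    max_area_cap: float = 10.0
    circ_min: float = 0.5


class RunConfig(_Strict):
    """Resolved configuration for a pipeline run."""

    seed: int = 0
    tier: Literal["tier1", "tier2", "tier3"] = "tier3"
    manure_fraction: float = 0.6
    landscape: LandscapeSection = LandscapeSection()
    climate: ClimateSection = ClimateSection()
    truth: TruthSection = TruthSection()
    search: SearchSection = SearchSection()
    emission: EmissionSection = EmissionSection()
    uncertainty: UncertaintySection = UncertaintySection()
    filter: FilterSection = FilterSection()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run configuration; missing file sections use defaults."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ValueError("config file must contain a mapping")
            data = raw
    data.update(overrides)
    return RunConfig(**data)
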