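"""Top-level simulation settings bundling every model input."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .indoor import EmissionFactorTable
from .outdoor import CongenerTable
from .population import PopulationConfig
from .risk import RiskConfig
from .scenarios import (
    DEFAULT_FUEL_ENERGY_MJ_PER_KG,
    Scenario,
    scenario_registry,
)

__all__ = ["Settings"]


@dataclass
class Settings:
    """Everything a Monte Carlo run needs, validated up front."""

    population: PopulationConfig
    congener_table: CongenerTable
    emission_factors: EmissionFactorTable
    risk: RiskConfig = RiskConfig()
    cleaner_cadr_m3_h: float = 134.0
    cleaner_hours_per_day: float = 16.0
    who_bap_guideline_ng_m3: float = 1.2
    who_bap_fraction: float = 0.381
    fuel_energy_mj_per_kg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUEL_ENERGY_MJ_PER_KG)
    )
    correlated_outdoor: bool = True
    lifetime_years: float = 70.0

    def validate(self) -> None:
        self.population.validate()
        self.risk.validate()
        if self.cleaner_cadr_m3_h < 0 or self.cleaner_hours_per_day < 0:
            raise ValueError("cleaner CADR and operating hours must be >= 0")
        if self.cleaner_hours_per_day > 24:
            raise ValueError("cleaner.hours_per_day cannot exceed 24")
        if not 0.0 < self.who_bap_fraction <= 1.0:
            raise ValueError("who.bap_fraction_of_baepeq must lie in (0, 1]")
        if self.lifetime_years <= 0:
            raise ValueError("lifetime_years must be > 0")
        for fuel, e in self.fuel_energy_mj_per_kg.items():
            if e <= 0:
                raise ValueError(f"fuel_energy_mj_per_kg.{fuel} must be > 0")

    def registry(self) -> tuple[Scenario, ...]:
        return scenario_registry(
            cleaner_cadr_m3_h=self.cleaner_cadr_m3_h,
            cleaner_hours_per_day=self.cleaner_hours_per_day,
            who_bap_guideline_ng_m3=self.who_bap_guideline_ng_m3,
            who_bap_fraction=self.who_bap_fraction,
        )

    def with_population(self, population: PopulationConfig) -> "Settings":
        return replace(self, population=population)

    def with_congener_table(self, table: CongenerTable) -> "Settings":
        return replace(self, congener_table=table)
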