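"""Intervention scenarios as declarative transformations of the baseline.

Fifteen scenarios are carried: two baselines (B-u, B-r) with empty
transforms, and thirteen interventions built from six primitive edits:

* ``RemoveSmoking`` — all smoking activity removed from residences and
  workplaces (SF-u / SF-r);
* ``FuelShift`` — a fraction of solid-fuel households re-provisioned with
  LPG at equal fuel energy content (CF-Hf-r / CF-All-r);
* ``OutdoorScale`` — outdoor concentrations multiplied by a factor
  (Atm-Hf-u, factor 0.5);
* ``OutdoorSetBaepeq`` — outdoor field uniformly rescaled per season so its
  B[a]Peq hits a guideline-derived target (Atm-WHO-u / Atm-WHO-r);
* ``SetERF`` — cooking emission-remaining factors capped at a value
  (Ex-u and Ex-80/50/20-r); capping (rather than overwriting) means
  households already venting better, e.g. coal users with chimneys at
  ERF 0.10, are never made worse;
* ``AddCADR`` — a particle cleaner added to every household of the
  sub-population, its clean-air delivery rate time-averaged over the hours
  it operates per day (IC-u / IC-r).

Edits are applied to the *sampled* state (an individual plus its outdoor
concentration draw), never to the random-number stream, so scenario pairs
under a common seed differ only through the edits themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

from .constants import HOURS_PER_DAY
from .outdoor import OutdoorConcField
from .population import Individual

__all__ = [
    "RemoveSmoking",
    "FuelShift",
    "OutdoorScale",
    "OutdoorSetBaepeq",
    "SetERF",
    "AddCADR",
    "Scenario",
    "who_target_baepeq",
    "scenario_registry",
    "get_scenario",
    "apply_scenario",
]

#: solid cooking fuels affected by clean-fuel and exhaust interventions
COOKING_FUELS = ("wood_crop", "coal", "lpg")

#: fuel energy content, MJ/kg, for energy-equivalent fuel substitution
DEFAULT_FUEL_ENERGY_MJ_PER_KG = {"wood_crop": 16.0, "coal": 23.0, "lpg": 46.0}


@dataclass(frozen=True)
class RemoveSmoking:
    pass


@dataclass(frozen=True)
class FuelShift:
    fraction: float                 # fraction of solid-fuel households shifted
    from_fuels: tuple[str, ...]
    to_fuel: str


@dataclass(frozen=True)
class OutdoorScale:
    factor: float


@dataclass(frozen=True)
class OutdoorSetBaepeq:
    target_ng_m3: float


@dataclass(frozen=True)
class SetERF:
    value: float                    # cap applied to every cooking fuel's ERF


@dataclass(frozen=True)
class AddCADR:
    cadr_m3_h: float
    hours_per_day: float

    @property
    def time_averaged(self) -> float:
        return self.cadr_m3_h * self.hours_per_day / HOURS_PER_DAY


Edit = Union[RemoveSmoking, FuelShift, OutdoorScale, OutdoorSetBaepeq, SetERF, AddCADR]


@dataclass(frozen=True)
class Scenario:
    id: str
    sub_population: str  # "urban" | "rural"
    description: str
    edits: tuple[Edit, ...] = ()

    @property
    def is_baseline(self) -> bool:
        return not self.edits


def who_target_baepeq(bap_guideline_ng_m3: float, bap_fraction: float) -> float:
    """B[a]Peq target equivalent to a BaP guideline value.

    The guideline is written for BaP as an indicator of the PAH mixture;
    dividing by the average share of BaP in total B[a]Peq converts it to a
    mixture-level B[a]Peq target.
    """
    if not 0.0 < bap_fraction <= 1.0:
        raise ValueError(
            f"BaP fraction of B[a]Peq must lie in (0, 1] (got {bap_fraction})"
        )
    if bap_guideline_ng_m3 < 0:
        raise ValueError("guideline value must be >= 0")
    return bap_guideline_ng_m3 / bap_fraction


def scenario_registry(
    cleaner_cadr_m3_h: float = 134.0,
    cleaner_hours_per_day: float = 16.0,
    who_bap_guideline_ng_m3: float = 1.2,
    who_bap_fraction: float = 0.381,
) -> tuple[Scenario, ...]:
    """The two baselines and thirteen interventions, ids as published."""
    who_target = who_target_baepeq(who_bap_guideline_ng_m3, who_bap_fraction)
    cleaner = AddCADR(cleaner_cadr_m3_h, cleaner_hours_per_day)
    shift = ("wood_crop", "coal")
    return (
        Scenario("B-u", "urban", "Baseline, urban"),
        Scenario("B-r", "rural", "Baseline, rural"),
        Scenario("SF-u", "urban", "All smoking activity removed",
                 (RemoveSmoking(),)),
        Scenario("SF-r", "rural", "All smoking activity removed",
                 (RemoveSmoking(),)),
        Scenario("CF-Hf-r", "rural",
                 "Half of rural solid-fuel use shifted to LPG",
                 (FuelShift(0.5, shift, "lpg"),)),
        Scenario("CF-All-r", "rural",
                 "All rural solid-fuel use shifted to LPG",
                 (FuelShift(1.0, shift, "lpg"),)),
        Scenario("Atm-Hf-u", "urban", "Outdoor PAH concentration halved",
                 (OutdoorScale(0.5),)),
        Scenario("Atm-WHO-u", "urban",
                 "Outdoor PAH concentration lowered to the WHO guideline",
                 (OutdoorSetBaepeq(who_target),)),
        Scenario("Atm-WHO-r", "rural",
                 "Outdoor PAH concentration lowered to the WHO guideline",
                 (OutdoorSetBaepeq(who_target),)),
        Scenario("Ex-u", "urban", "Exhaust hoods used in all urban households",
                 (SetERF(0.5),)),
        Scenario("Ex-80-r", "rural", "Only 80% of cooking emissions remain indoors",
                 (SetERF(0.8),)),
        Scenario("Ex-50-r", "rural", "Only 50% of cooking emissions remain indoors",
                 (SetERF(0.5),)),
        Scenario("Ex-20-r", "rural", "Only 20% of cooking emissions remain indoors",
                 (SetERF(0.2),)),
        Scenario("IC-u", "urban", "Average particle cleaner added indoors",
                 (cleaner,)),
        Scenario("IC-r", "rural", "Average particle cleaner added indoors",
                 (cleaner,)),
    )


def get_scenario(scenario_id: str, registry: tuple[Scenario, ...] | None = None) -> Scenario:
    registry = registry if registry is not None else scenario_registry()
    for s in registry:
        if s.id == scenario_id:
            return s
    valid = ", ".join(s.id for s in registry)
    raise ValueError(f"unknown scenario id {scenario_id!r}; valid ids: {valid}")


def _apply_fuel_shift(individual: Individual, edit: FuelShift,
                      fuel_energy: Mapping[str, float]) -> None:
    hh = individual.household
    solid = sum(hh.fuel_use.get(f, 0.0) for f in edit.from_fuels)
    if solid <= 0 or individual.cf_lottery >= edit.fraction:
        return
    energy = sum(
        hh.fuel_use.get(f, 0.0) * fuel_energy[f] for f in edit.from_fuels
    )
    for f in edit.from_fuels:
        hh.fuel_use[f] = 0.0
    hh.fuel_use[edit.to_fuel] = (
        hh.fuel_use.get(edit.to_fuel, 0.0) + energy / fuel_energy[edit.to_fuel]
    )
    hh.fuel_erf.setdefault(edit.to_fuel, 1.0)


def apply_scenario(
    scenario: Scenario,
    individual: Individual,
    outdoor_field: OutdoorConcField,
    tefs,
    fuel_energy: Mapping[str, float] | None = None,
) -> tuple[Individual, OutdoorConcField]:
    """Apply a scenario's edits to one sampled replicate.

    Returns a transformed copy; the inputs are never mutated, and no random
    numbers are consumed (the fuel-shift lottery deviate was drawn at
    sampling time), so common-random-number pairing with the baseline is
    exact.  Baseline scenarios return the inputs unchanged.
    """
    if scenario.is_baseline:
        return individual, outdoor_field
    fuel_energy = fuel_energy or DEFAULT_FUEL_ENERGY_MJ_PER_KG
    ind = individual.copy()
    field = outdoor_field
    for edit in scenario.edits:
        if isinstance(edit, RemoveSmoking):
            ind.household.smoking_cigarettes_per_day = 0.0
            ind.workplace.smoking_cigarettes_per_day = 0.0
        elif isinstance(edit, FuelShift):
            _apply_fuel_shift(ind, edit, fuel_energy)
        elif isinstance(edit, OutdoorScale):
            field = field.scaled(edit.factor)
        elif isinstance(edit, OutdoorSetBaepeq):
            field = field.rescaled_to_baepeq(edit.target_ng_m3, tefs)
        elif isinstance(edit, SetERF):
            for fuel in ind.household.fuel_erf:
                ind.household.fuel_erf[fuel] = min(
                    ind.household.fuel_erf[fuel], edit.value
                )
        elif isinstance(edit, AddCADR):
            ind.household.cadr += edit.time_averaged
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown scenario edit {edit!r}")
    return ind, field
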