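"""Synthetic individuals and households for the population exposure model.

Each Monte Carlo replicate is one simulated person: a region (urban/rural),
demographic flags, a household environment (floor area, infiltration
air-exchange rate, penetration coefficient, cooking fuels, environmental
tobacco smoke), a workplace environment, and a three-microenvironment
time-activity budget (home indoor / work-school indoor / outdoor) that closes
to 24 h exactly.

Distribution families
---------------------
Parameter tables in this field report a central value and an SD without
naming a law.  Physically non-negative, roughly symmetric quantities (time,
floor area, penetration, air-exchange rate) are sampled from normals
truncated at their physical bounds; heavy-right-tailed quantities whose SD
exceeds the mean (household smoking quantity, fuel use) are sampled from
lognormals matched to the (mean, SD) moments.

Sampling draws occur in a fixed, documented order and every potentially
needed deviate is drawn for every individual, so that two runs with the same
seed but different central values (or different downstream scenario edits)
consume identical random-number streams — the common-random-number
discipline that the intervention comparisons and sensitivity sweeps rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm as _truncnorm

from .constants import HOURS_PER_DAY, MICROENVS, REGIONS

__all__ = [
    "ParamSpec",
    "RegionParams",
    "WorkplaceParams",
    "BreathingParams",
    "PopulationConfig",
    "HouseholdEnv",
    "TimeBudget",
    "Individual",
    "sample_individual",
    "sample_population",
    "build_time_budget",
]


@dataclass(frozen=True)
class ParamSpec:
    """A sampled scalar parameter: central value, SD, family and bounds."""

    mean: float
    sd: float
    family: str = "truncnorm"  # "truncnorm" | "lognormal"
    low: float = 0.0
    high: float = math.inf

    def validate(self, key: str = "parameter") -> None:
        if self.sd < 0:
            raise ValueError(f"{key}.sd must be >= 0 (got {self.sd})")
        if self.family not in ("truncnorm", "lognormal"):
            raise ValueError(f"{key}.family must be 'truncnorm' or 'lognormal'")
        if not self.low < self.high:
            raise ValueError(f"{key}: truncation bounds must satisfy low < high")

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value; consumes exactly one uniform from ``rng``."""
        u = rng.random()
        return self._from_uniform(u)

    def _from_uniform(self, u: float) -> float:
        if self.family == "lognormal":
            if self.mean <= 0:
                return 0.0
            if self.sd == 0:
                return self.mean
            ratio = self.sd / self.mean
            # log1p overflows for extreme SD/mean ratios; use the asymptote
            sigma2 = (
                math.log1p(ratio**2) if ratio < 1e100 else 2.0 * math.log(ratio)
            )
            mu = math.log(self.mean) - sigma2 / 2.0
            x = math.exp(mu + math.sqrt(sigma2) * ndtri(min(max(u, 1e-12), 1 - 1e-12)))
            return min(x, self.high) if math.isfinite(self.high) else x
        # truncated normal
        if self.sd == 0:
            return min(max(self.mean, self.low), self.high)
        a = ndtr((self.low - self.mean) / self.sd)
        b = ndtr((self.high - self.mean) / self.sd) if math.isfinite(self.high) else 1.0
        x = self.mean + self.sd * ndtri(a + u * (b - a))
        return min(max(x, self.low), self.high)

    def distribution_mean(self) -> float:
        """Analytic mean of the configured (possibly truncated) distribution."""
        if self.family == "lognormal":
            return max(self.mean, 0.0)
        if self.sd == 0:
            return min(max(self.mean, self.low), self.high)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd if math.isfinite(self.high) else np.inf
        return float(_truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    def shifted(self, n_sd: float) -> "ParamSpec":
        """Central value moved by ``n_sd`` standard deviations, SD kept."""
        return replace(self, mean=self.mean + n_sd * self.sd)


@dataclass(frozen=True)
class RegionParams:
    """Per-region parameter distributions and prevalence fractions."""

    ach: ParamSpec                      # infiltration air-exchange rate, 1/h
    floor_area_m2: ParamSpec            # residential floor area
    penetration: ParamSpec              # particle penetration coefficient
    time_home_h: ParamSpec              # h/day at home indoors
    time_work_school_h: ParamSpec       # h/day at work or school
    smoking_cigs_per_day: ParamSpec     # household total, cigarettes/day
    wood_crop_kg_day: ParamSpec
    coal_kg_day: ParamSpec
    lpg_kg_day: ParamSpec
    coal_user_fraction: float           # within-region prevalence of coal use
    hood_user_fraction: float           # regular exhaust-hood users
    home_smoking_ban_fraction: float
    workplace_smoking_ban_fraction: float

    def validate(self, key: str = "region") -> None:
        for name in (
            "ach", "floor_area_m2", "penetration", "time_home_h",
            "time_work_school_h", "smoking_cigs_per_day",
            "wood_crop_kg_day", "coal_kg_day", "lpg_kg_day",
        ):
            getattr(self, name).validate(f"{key}.{name}")
        for name in (
            "coal_user_fraction", "hood_user_fraction",
            "home_smoking_ban_fraction", "workplace_smoking_ban_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{key}.{name} must be a proportion in [0, 1] (got {v})")


@dataclass(frozen=True)
class WorkplaceParams:
    """Simplified shared-indoor environment for the employed and students."""

    ach: float = 1.0          # 1/h
    volume_m3: float = 30.0   # per occupant
    penetration: float = 0.9

    def validate(self) -> None:
        if self.ach <= 0 or self.volume_m3 <= 0:
            raise ValueError("workplace.ach and workplace.volume_m3 must be > 0")
        if not 0.0 <= self.penetration <= 1.0:
            raise ValueError("workplace.penetration must lie in [0, 1]")


@dataclass(frozen=True)
class BreathingParams:
    """Long-term inhalation volume allocated by microenvironment activity."""

    daily_volume_m3: float = 16.0
    multipliers: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.multipliers is None:
            object.__setattr__(
                self, "multipliers", {"home": 0.8, "work": 1.0, "outdoor": 1.5}
            )

    def rate(self, microenv: str) -> float:
        """Ventilation rate (m3/h) while in ``microenv``."""
        return self.daily_volume_m3 / HOURS_PER_DAY * self.multipliers[microenv]

    def validate(self) -> None:
        if self.daily_volume_m3 <= 0:
            raise ValueError("breathing.daily_volume_m3 must be > 0")
        for m in MICROENVS:
            if self.multipliers.get(m, 0) <= 0:
                raise ValueError(f"breathing.multipliers.{m} must be > 0")


@dataclass(frozen=True)
class PopulationConfig:
    """Demographics, per-region parameter distributions and household physics."""

    urban_fraction: float
    male_fraction: float
    smoker_fraction: float
    employed_fraction: float
    school_age_fraction: float
    regions: Mapping[str, RegionParams]
    workplace: WorkplaceParams = WorkplaceParams()
    breathing: BreathingParams = BreathingParams()
    ceiling_height_m: float = 2.7
    deposition_rate_particle: float = 0.2  # 1/h, particle phase only
    erf_chimney: float = 0.10   # emission-remaining factor, coal + chimney
    erf_hood: float = 0.50      # emission-remaining factor, exhaust-hood users

    def validate(self) -> None:
        for name in (
            "urban_fraction", "male_fraction", "smoker_fraction",
            "employed_fraction", "school_age_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"population.{name} must be a proportion in [0, 1] (got {v})")
        for name in ("erf_chimney", "erf_hood"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"population.{name} must lie in [0, 1] (got {v})")
        if self.ceiling_height_m <= 0:
            raise ValueError("population.ceiling_height_m must be > 0")
        if self.deposition_rate_particle < 0:
            raise ValueError("population.deposition_rate_particle must be >= 0")
        for region in REGIONS:
            if region not in self.regions:
                raise ValueError(f"population.regions must define '{region}'")
            self.regions[region].validate(f"population.regions.{region}")
        self.workplace.validate()
        self.breathing.validate()

    @property
    def employed_or_student_fraction(self) -> float:
        return self.employed_fraction + self.school_age_fraction


@dataclass
class HouseholdEnv:
    """Single-zone indoor environment at steady state.

    ``cadr`` is the *time-averaged* clean-air delivery rate of any particle
    cleaner (m3/h over 24 h); 0 at baseline.  ``fuel_use`` maps fuel name to
    kg/day and ``fuel_erf`` to the emission-remaining factor applied to that
    fuel's cooking emissions (1 = everything stays indoors).
    """

    floor_area: float            # m2
    ceiling_height: float        # m
    ach: float                   # 1/h infiltration air-exchange rate
    penetration: float           # particle penetration coefficient, [0, 1]
    deposition_rate_particle: float  # 1/h
    cadr: float = 0.0            # m3/h, time-averaged
    fuel_use: dict[str, float] = field(default_factory=dict)
    fuel_erf: dict[str, float] = field(default_factory=dict)
    smoking_cigarettes_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.floor_area <= 0 or self.ceiling_height <= 0:
            raise ValueError("floor area and ceiling height must be > 0")
        if not 0.0 <= self.penetration <= 1.0:
            raise ValueError("penetration coefficient must lie in [0, 1]")
        for name in ("ach", "deposition_rate_particle", "cadr",
                     "smoking_cigarettes_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for fuel, erf in self.fuel_erf.items():
            if not 0.0 <= erf <= 1.0:
                raise ValueError(f"fuel_erf[{fuel!r}] must lie in [0, 1]")

    @property
    def volume(self) -> float:
        """m3; derived so volume = floor_area x ceiling_height always holds."""
        return self.floor_area * self.ceiling_height

    def copy(self) -> "HouseholdEnv":
        return replace(self, fuel_use=dict(self.fuel_use), fuel_erf=dict(self.fuel_erf))


@dataclass(frozen=True)
class TimeBudget:
    """Daily hours per microenvironment; closes to 24 h exactly."""

    hours_home_indoor: float
    hours_work_school_indoor: float
    hours_outdoor: float

    def __post_init__(self) -> None:
        for v in (self.hours_home_indoor, self.hours_work_school_indoor,
                  self.hours_outdoor):
            if v < 0:
                raise ValueError("time-budget components must be >= 0")
        total = (self.hours_home_indoor + self.hours_work_school_indoor
                 + self.hours_outdoor)
        if abs(total - HOURS_PER_DAY) > 1e-9:
            raise ValueError(f"time budget must sum to 24 h (got {total})")


@dataclass
class Individual:
    """One simulated person; the carrier of all sampled attributes."""

    region: str
    is_smoker: bool
    is_employed_or_student: bool
    household: HouseholdEnv
    workplace: HouseholdEnv
    time_budget: TimeBudget
    breathing_rate_by_microenv: dict[str, float]
    #: uniform deviate reserved for fuel-shift scenario selection, drawn at
    #: sampling time so scenario application never consumes randomness
    cf_lottery: float = 1.0

    def copy(self) -> "Individual":
        return replace(
            self,
            household=self.household.copy(),
            workplace=self.workplace.copy(),
            breathing_rate_by_microenv=dict(self.breathing_rate_by_microenv),
        )


def build_time_budget(
    is_employed_or_student: bool,
    params: RegionParams,
    rng: np.random.Generator,
) -> TimeBudget:
    """Draw a closed 24-h budget over home / work-school / outdoor.

    Home hours are drawn first (centred on 16 h/day, the typical time spent
    at home), then work/school hours truncated into the remaining day; the
    outdoor remainder absorbs the rest, so closure is exact and all
    components are non-negative by construction.  Individuals who are
    neither employed nor in school have their drawn work hours reallocated
    to home (both draws always happen, keeping the random stream aligned).
    """
    home = params.time_home_h._from_uniform(rng.random())
    home = min(home, HOURS_PER_DAY)
    work_spec = replace(params.time_work_school_h, low=0.0,
                        high=HOURS_PER_DAY - home)
    work = work_spec._from_uniform(rng.random()) if home < HOURS_PER_DAY else 0.0
    if not is_employed_or_student:
        home, work = home + work, 0.0
    outdoor = max(HOURS_PER_DAY - home - work, 0.0)
    return TimeBudget(home, work, outdoor)


def sample_individual(
    region: str,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> Individual:
    """Sample one individual with household and workplace environments.

    Draws occur in a fixed order (demographics, household physics, smoking,
    fuels, workplace, time budget, scenario lottery); every draw happens for
    every individual regardless of branch outcomes, so streams stay aligned
    across configurations that share a seed.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    p = config.regions[region]

    u_smoker = rng.random()
    u_employed = rng.random()
    floor_area = p.floor_area_m2.sample(rng)
    ach = p.ach.sample(rng)
    penetration = p.penetration.sample(rng)
    smoking_qty = p.smoking_cigs_per_day.sample(rng)
    u_home_ban = rng.random()
    wood_qty = p.wood_crop_kg_day.sample(rng)
    u_coal = rng.random()
    coal_qty = p.coal_kg_day.sample(rng)
    lpg_qty = p.lpg_kg_day.sample(rng)
    u_hood = rng.random()
    work_smoking_qty = p.smoking_cigs_per_day.sample(rng)
    u_work_ban = rng.random()

    is_smoker = u_smoker < config.smoker_fraction
    is_employed = u_employed < config.employed_or_student_fraction
    is_coal_user = u_coal < p.coal_user_fraction
    uses_hood = u_hood < p.hood_user_fraction
    home_ban = u_home_ban < p.home_smoking_ban_fraction
    work_ban = u_work_ban < p.workplace_smoking_ban_fraction

    fuel_use = {
        "wood_crop": wood_qty,
        "coal": coal_qty if is_coal_user else 0.0,
        "lpg": lpg_qty,
    }
    fuel_erf = {
        "wood_crop": 1.0,
        "coal": config.erf_chimney if is_coal_user else 1.0,
        "lpg": config.erf_hood if uses_hood else 1.0,
    }
    household = HouseholdEnv(
        floor_area=max(floor_area, 1.0),
        ceiling_height=config.ceiling_height_m,
        ach=ach,
        penetration=penetration,
        deposition_rate_particle=config.deposition_rate_particle,
        fuel_use=fuel_use,
        fuel_erf=fuel_erf,
        smoking_cigarettes_per_day=0.0 if home_ban else smoking_qty,
    )
    wp = config.workplace
    workplace = HouseholdEnv(
        floor_area=wp.volume_m3 / config.ceiling_height_m,
        ceiling_height=config.ceiling_height_m,
        ach=wp.ach,
        penetration=wp.penetration,
        deposition_rate_particle=config.deposition_rate_particle,
        smoking_cigarettes_per_day=0.0 if work_ban else work_smoking_qty,
    )
    time_budget = build_time_budget(is_employed, p, rng)
    u_cf = rng.random()

    return Individual(
        region=region,
        is_smoker=is_smoker,
        is_employed_or_student=is_employed,
        household=household,
        workplace=workplace,
        time_budget=time_budget,
        breathing_rate_by_microenv={m: config.breathing.rate(m) for m in MICROENVS},
        cf_lottery=u_cf,
    )


def sample_population(
    n: int,
    config: PopulationConfig,
    seed: int | np.random.Generator,
    region: str | None = None,
) -> list[Individual]:
    """Sample ``n`` individuals, deterministically under a fixed seed.

    With ``region`` fixed, all individuals belong to that sub-population
    (urban and rural runs are performed separately); with ``region=None``
    each individual's region is assigned by the configured urban fraction.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1 (got {n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if region is None:
            r = "urban" if rng.random() < config.urban_fraction else "rural"
        else:
            r = region
        out.append(sample_individual(r, config, rng))
    return out
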