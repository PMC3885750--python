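"""Seeded Monte Carlo driver: scenario runs, comparisons, sensitivity sweeps.

One replicate is one simulated individual.  The urban and rural
sub-populations are simulated separately, each against its own baseline.
A cohort (individuals plus their outdoor concentration draws) is sampled
once per (seed, sub-population) and shared by every scenario that touches
it: scenario edits are deterministic transforms of the sampled state, so
paired per-individual differences between scenarios carry no Monte Carlo
noise beyond the edit itself (common random numbers).

Summaries report, per scenario, the mean, interquartile range (P25/P75) and
95% upper limit (P95, linear-interpolation quantile rule) of home indoor
B[a]Peq, the home I/O ratio and the annual inhalation dose, together with
the population-mean relative risk, PAF, the exposure-pattern statistics and
— for interventions — the PIF against the sub-population's baseline.

The one-at-a-time sensitivity sweep shifts one parameter's central value by
±1 SD (its SD untouched), re-runs every scenario under the same seed and
reports the percentage change in mean annual dose plus the resulting PIF
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Settings
from .constants import REGIONS
from .exposure import ExposureResult, PatternSummary, annual_metrics, pattern_statistics
from .indoor import build_emission_inventory, steady_state_concentration
from .outdoor import OutdoorConcField, sample_outdoor_field
from .population import Individual, sample_individual
from .risk import (
    mean_relative_risk,
    population_attributable_fraction,
    potential_impact_fraction,
    urr_sensitivity_table,
)
from .scenarios import Scenario, apply_scenario, get_scenario

__all__ = [
    "Cohort",
    "ScenarioSummary",
    "SensitivityResult",
    "ComparisonResult",
    "sample_cohort",
    "run_scenario",
    "compare_scenarios",
    "run_comparison",
    "sensitivity_sweep",
    "SENSITIVITY_PARAMETERS",
]

_REGION_STREAM = {"urban": 0, "rural": 1}


@dataclass
class Cohort:
    """A sampled sub-population with per-replicate outdoor fields."""

    region: str
    seed: int
    individuals: list[Individual]
    outdoor_fields: list[OutdoorConcField]

    def __len__(self) -> int:
        return len(self.individuals)


def sample_cohort(settings: Settings, region: str, n_reps: int, seed: int) -> Cohort:
    """Sample ``n_reps`` individuals of one region plus their outdoor draws.

    The stream is keyed by (seed, region) only, so every scenario of the
    same sub-population and seed sees an identical cohort.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1 (got {n_reps})")
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    rng = np.random.default_rng([seed, _REGION_STREAM[region]])
    individuals = []
    fields = []
    for _ in range(n_reps):
        individuals.append(sample_individual(region, settings.population, rng))
        fields.append(
            sample_outdoor_field(
                settings.congener_table, rng, correlated=settings.correlated_outdoor
            )
        )
    return Cohort(region=region, seed=seed, individuals=individuals,
                  outdoor_fields=fields)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    p25: float
    p75: float
    p95: float

    @classmethod
    def of(cls, values: np.ndarray) -> "SummaryStats":
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            return cls(np.nan, np.nan, np.nan, np.nan)
        q25, q75, q95 = np.quantile(finite, [0.25, 0.75, 0.95])
        return cls(float(finite.mean()), float(q25), float(q75), float(q95))


@dataclass
class ScenarioSummary:
    """Distributional and risk summaries of one scenario run."""

    scenario_id: str
    sub_population: str
    n_reps: int
    seed: int
    home_baepeq: SummaryStats
    io_ratio: SummaryStats
    annual_dose: SummaryStats
    mean_rr: float
    paf: float
    pattern: PatternSummary
    c_life: np.ndarray = field(repr=False)
    values: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    results: list[ExposureResult] | None = field(default=None, repr=False)


def _simulate_individual(
    settings: Settings,
    scenario: Scenario,
    individual: Individual,
    outdoor_field: OutdoorConcField,
) -> ExposureResult:
    table = settings.congener_table
    ind, field_ = apply_scenario(
        scenario, individual, outdoor_field, table.tefs,
        settings.fuel_energy_mj_per_kg,
    )
    pf = table.particle_fraction
    c_gas = field_.gas(pf)
    c_part = field_.particle(pf)
    home_inv = build_emission_inventory(ind.household, settings.emission_factors)
    home = steady_state_concentration(ind.household, c_gas, c_part, home_inv)
    work_inv = build_emission_inventory(ind.workplace, settings.emission_factors)
    work = steady_state_concentration(ind.workplace, c_gas, c_part, work_inv)
    return annual_metrics(
        ind, home, work, field_, table.tefs, settings.lifetime_years
    )


def run_scenario(
    settings: Settings,
    scenario: str | Scenario,
    n_reps: int = 10_000,
    seed: int = 0,
    cohort: Cohort | None = None,
    keep_individuals: bool = False,
) -> ScenarioSummary:
    """Run one scenario over a (possibly shared) cohort and summarize it.

    Fully reproducible: the same settings, scenario, ``n_reps`` and ``seed``
    give an identical summary.  Pass a pre-sampled ``cohort`` to share the
    random draws with other scenarios of the same sub-population.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario, settings.registry())
    if cohort is None:
        cohort = sample_cohort(settings, scenario.sub_population, n_reps, seed)
    elif cohort.region != scenario.sub_population:
        raise ValueError(
            f"scenario {scenario.id!r} targets {scenario.sub_population!r} but "
            f"the cohort holds {cohort.region!r} individuals"
        )
    results = []
    for ind, fld in zip(cohort.individuals, cohort.outdoor_fields):
        try:
            results.append(_simulate_individual(settings, scenario, ind, fld))
        except ValueError as exc:
            raise ValueError(f"scenario {scenario.id!r}: {exc}") from exc

    home = np.array([r.home_baepeq_ng_m3 for r in results])
    outdoor = np.array([r.outdoor_baepeq_ng_m3 for r in results])
    dose = np.array([r.annual_dose_ug for r in results])
    c_life = np.array([r.lifetime_conc_ug_m3_year for r in results])
    with np.errstate(divide="ignore", invalid="ignore"):
        io = np.where(outdoor > 0, home / outdoor, np.nan)

    mean_rr = mean_relative_risk(
        c_life, settings.risk.urr, settings.risk.reference_exposure
    )
    return ScenarioSummary(
        scenario_id=scenario.id,
        sub_population=scenario.sub_population,
        n_reps=len(cohort),
        seed=cohort.seed,
        home_baepeq=SummaryStats.of(home),
        io_ratio=SummaryStats.of(io),
        annual_dose=SummaryStats.of(dose),
        mean_rr=mean_rr,
        paf=population_attributable_fraction(mean_rr),
        pattern=pattern_statistics(results),
        c_life=c_life,
        values={"home_baepeq": home, "io_ratio": io, "annual_dose": dose},
        results=results if keep_individuals else None,
    )


def compare_scenarios(
    baseline: ScenarioSummary,
    interventions: Sequence[ScenarioSummary],
) -> pd.DataFrame:
    """Ranking table: PIF (descending) against a shared baseline.

    Ties in PIF are broken by scenario id, lexicographically.  The table
    also carries the remaining PAF and its percentage reduction from the
    baseline PAF.
    """
    rows = []
    for s in interventions:
        if s.sub_population != baseline.sub_population:
            raise ValueError(
                f"cannot compare {s.scenario_id!r} ({s.sub_population}) against "
                f"baseline {baseline.scenario_id!r} ({baseline.sub_population})"
            )
        pif = potential_impact_fraction(baseline.mean_rr, s.mean_rr)
        rows.append(
            {
                "scenario": s.scenario_id,
                "sub_population": s.sub_population,
                "baseline": baseline.scenario_id,
                "pif": pif,
                "paf_remaining": s.paf,
                "paf_baseline": baseline.paf,
                "pct_paf_reduction": (
                    100.0 * (baseline.paf - s.paf) / baseline.paf
                    if baseline.paf > 0 else np.nan
                ),
                "mean_rr": s.mean_rr,
                "mean_annual_dose_ug": s.annual_dose.mean,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["pif", "scenario"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


@dataclass
class ComparisonResult:
    """All scenario summaries plus per-sub-population rankings."""

    summaries: dict[str, ScenarioSummary]
    rankings: dict[str, pd.DataFrame]      # sub-population -> ranking table
    baselines: dict[str, str]              # sub-population -> baseline id
    n_reps: int
    seed: int

    def risk_table(self, settings: Settings) -> pd.DataFrame:
        sub_pop = {sid: s.sub_population for sid, s in self.summaries.items()}
        return urr_sensitivity_table(
            {sid: s.c_life for sid, s in self.summaries.items()},
            sub_pop,
            self.baselines,
            settings.risk,
        )


_BASELINE_OF_REGION = {"urban": "B-u", "rural": "B-r"}


def run_comparison(
    settings: Settings,
    scenario_ids: Sequence[str] | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    keep_individuals: bool = False,
) -> ComparisonResult:
    """Run a scenario set (default: all 15) with shared per-region cohorts."""
    registry = settings.registry()
    if scenario_ids is None:
        scenario_ids = [s.id for s in registry]
    scenarios = [get_scenario(sid, registry) for sid in scenario_ids]

    needed_regions = {s.sub_population for s in scenarios}
    ids = {s.id for s in scenarios}
    for region in needed_regions:
        if _BASELINE_OF_REGION[region] not in ids:
            scenarios.append(get_scenario(_BASELINE_OF_REGION[region], registry))
            ids.add(_BASELINE_OF_REGION[region])

    cohorts = {
        region: sample_cohort(settings, region, n_reps, seed)
        for region in sorted(needed_regions)
    }
    summaries: dict[str, ScenarioSummary] = {}
    for scenario in scenarios:
        summaries[scenario.id] = run_scenario(
            settings, scenario, n_reps=n_reps, seed=seed,
            cohort=cohorts[scenario.sub_population],
            keep_individuals=keep_individuals,
        )
    baselines = {
        region: _BASELINE_OF_REGION[region] for region in sorted(needed_regions)
    }
    rankings = {}
    for region, baseline_id in baselines.items():
        interventions = [
            s for s in summaries.values()
            if s.sub_population == region and s.scenario_id != baseline_id
        ]
        if interventions:
            rankings[region] = compare_scenarios(summaries[baseline_id], interventions)
    return ComparisonResult(
        summaries=summaries, rankings=rankings, baselines=baselines,
        n_reps=n_reps, seed=seed,
    )


# --- one-at-a-time sensitivity sweep ---------------------------------------

def _shift_region_param(settings: Settings, name: str, d: float) -> Settings:
    pop = settings.population
    regions = dict(pop.regions)
    for region, params in regions.items():
        spec = getattr(params, name)
        regions[region] = _dc_replace(params, **{name: spec.shifted(d)})
    return settings.with_population(_dc_replace(pop, regions=regions))


def _shift_winter_bap(settings: Settings, d: float) -> Settings:
    table = settings.congener_table
    medians = table.medians.copy()
    si = table.seasons.index("winter")
    ci = table.congeners.index("BaP")
    shifted = medians[si, ci] + d * table.sds[si, ci]
    # a non-positive shifted median degenerates to a point mass at zero
    medians[si, ci] = max(shifted, 0.0)
    return settings.with_congener_table(table.with_medians(medians))


SENSITIVITY_PARAMETERS: Mapping[str, Callable[[Settings, float], Settings]] = {
    "infiltration_ach": lambda s, d: _shift_region_param(s, "ach", d),
    "outdoor_bap_winter": _shift_winter_bap,
    "residential_area": lambda s, d: _shift_region_param(s, "floor_area_m2", d),
    "wood_crop_quantity": lambda s, d: _shift_region_param(s, "wood_crop_kg_day", d),
    "time_work_school": lambda s, d: _shift_region_param(s, "time_work_school_h", d),
    "penetration": lambda s, d: _shift_region_param(s, "penetration", d),
    "smoking_quantity": lambda s, d: _shift_region_param(s, "smoking_cigs_per_day", d),
}


@dataclass(frozen=True)
class SensitivityResult:
    """Effect of a ±1 SD central-value shift in one parameter."""

    parameter: str
    direction: str                       # "+SD" | "-SD"
    pct_change_dose: Mapping[str, float]  # scenario id -> % change in mean dose
    ranking: Mapping[str, tuple[str, ...]]  # sub-population -> ids by PIF desc


def sensitivity_sweep(
    settings: Settings,
    scenario_ids: Sequence[str] | None = None,
    parameters: Sequence[str] | None = None,
    n_reps: int = 2_000,
    seed: int = 0,
) -> list[SensitivityResult]:
    """±1 SD one-at-a-time sweep under common random numbers.

    Each parameter's central value is shifted by ±1 SD (the SD itself is
    kept), every scenario is re-run under the unchanged seed, and the
    percentage change of the mean annual dose against the unshifted run is
    reported together with the PIF ranking under the shift.
    """
    parameters = list(parameters) if parameters is not None else list(
        SENSITIVITY_PARAMETERS
    )
    unknown = [p for p in parameters if p not in SENSITIVITY_PARAMETERS]
    if unknown:
        raise ValueError(
            f"unknown sensitivity parameter(s) {unknown}; valid keys: "
            f"{sorted(SENSITIVITY_PARAMETERS)}"
        )
    base = run_comparison(settings, scenario_ids, n_reps=n_reps, seed=seed)
    base_dose = {
        sid: s.annual_dose.mean for sid, s in base.summaries.items()
    }
    out = []
    for param in parameters:
        for d, label in ((+1.0, "+SD"), (-1.0, "-SD")):
            shifted = SENSITIVITY_PARAMETERS[param](settings, d)
            run = run_comparison(shifted, scenario_ids, n_reps=n_reps, seed=seed)
            pct = {
                sid: (
                    100.0 * (s.annual_dose.mean - base_dose[sid]) / base_dose[sid]
                    if base_dose[sid] > 0 else 0.0
                )
                for sid, s in run.summaries.items()
            }
            ranking = {
                region: tuple(table["scenario"])
                for region, table in run.rankings.items()
            }
            out.append(
                SensitivityResult(
                    parameter=param, direction=label,
                    pct_change_dose=pct, ranking=ranking,
                )
            )
    return out
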