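"""Integration of concentrations over the time-activity budget.

Exposure in a microenvironment is the product of concentration, time spent
there and pulmonary ventilation rate while there.  Per individual the module
produces:

* the annual inhaled dose of B[a]Peq (µg/year),
* the 24-h, season-averaged time-weighted B[a]Peq concentration (ng/m3),
* the lifetime exposure concentration C (µg/m3·year) that enters the
  relative-risk model — concentration-years, because the unit relative risk
  is defined against a lifetime exposure of 100 µg/m3·year,
* the IN-in / OUT-in / OUT-out decomposition: the fractions of total
  exposure received indoors from indoor-origin pollutant, indoors from
  outdoor-origin pollutant, and outdoors.  (IN-out — one household's own
  emissions re-encountered outdoors — is negligible and not modelled.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .constants import DAYS_PER_SEASON, HOURS_PER_DAY, N_CONGENERS, N_SEASONS, PATTERNS
from .indoor import IndoorConc
from .outdoor import OutdoorConcField
from .population import Individual

__all__ = [
    "PatternShares",
    "ExposureResult",
    "PatternSummary",
    "microenvironment_exposure",
    "annual_metrics",
    "lifetime_concentration",
    "pattern_statistics",
]

#: fixed priority for breaking exact dominance ties (measure-zero under
#: continuous sampling); highest priority first
_TIE_PRIORITY = ("OUT_in", "IN_in", "OUT_out")


class PatternShares(NamedTuple):
    IN_in: float
    OUT_in: float
    OUT_out: float


@dataclass(frozen=True)
class ExposureResult:
    """Annual exposure metrics for one simulated individual."""

    annual_dose_ug: float              # µg B[a]Peq inhaled per year
    time_weighted_conc_ng_m3: float    # season-averaged 24-h TWA, ng/m3
    lifetime_conc_ug_m3_year: float    # C in the risk model, µg/m3·year
    pattern_shares: PatternShares
    home_baepeq_ng_m3: float           # annual mean home indoor B[a]Peq
    outdoor_baepeq_ng_m3: float        # annual mean outdoor B[a]Peq


def microenvironment_exposure(conc: float, hours: float, vent: float) -> float:
    """Inhaled amount (ng) = concentration x time x ventilation rate."""
    if conc < 0 or hours < 0 or vent < 0:
        raise ValueError("concentration, hours and ventilation must be >= 0")
    return conc * hours * vent


def lifetime_concentration(
    time_weighted_conc_ng_m3: float, lifetime_years: float
) -> float:
    """Lifetime exposure concentration, µg/m3·year (ng -> µg conversion)."""
    if time_weighted_conc_ng_m3 < 0 or lifetime_years < 0:
        raise ValueError("inputs must be >= 0")
    return time_weighted_conc_ng_m3 * lifetime_years / 1000.0


def _check_seasonal(arr: np.ndarray, name: str) -> None:
    if arr.shape != (N_SEASONS, N_CONGENERS):
        raise ValueError(
            f"{name} must provide all {N_SEASONS} seasons x {N_CONGENERS} "
            f"congeners (got shape {arr.shape})"
        )


def annual_metrics(
    individual: Individual,
    indoor_home: IndoorConc,
    indoor_work: IndoorConc,
    outdoor_field: OutdoorConcField,
    tefs: np.ndarray,
    lifetime_years: float = 70.0,
) -> ExposureResult:
    """Integrate seasonal microenvironment concentrations into annual metrics.

    The four seasons carry equal weight (91.25 days each).  The pattern
    decomposition is exposure-weighted: indoor dose contributions are split
    by the indoor-origin / outdoor-origin components of the steady-state
    concentration, and outdoor dose is outdoor-origin by definition.  For an
    individual with zero total exposure the shares are reported as all-zero.
    """
    _check_seasonal(indoor_home.gas_outdoor, "indoor_home")
    _check_seasonal(indoor_work.gas_outdoor, "indoor_work")

    tb = individual.time_budget
    v = individual.breathing_rate_by_microenv
    t_home, t_work, t_out = (
        tb.hours_home_indoor,
        tb.hours_work_school_indoor,
        tb.hours_outdoor,
    )

    home_in = indoor_home.indoor_origin @ tefs    # (4,) ng/m3
    home_out = indoor_home.outdoor_origin @ tefs
    work_in = indoor_work.indoor_origin @ tefs
    work_out = indoor_work.outdoor_origin @ tefs
    out_conc = outdoor_field.baepeq_by_season(tefs)

    # daily inhaled ng per season, by pattern
    d_in_in = (home_in * t_home * v["home"] + work_in * t_work * v["work"])
    d_out_in = (home_out * t_home * v["home"] + work_out * t_work * v["work"])
    d_out_out = out_conc * t_out * v["outdoor"]

    in_in = float(d_in_in.sum())
    out_in = float(d_out_in.sum())
    out_out = float(d_out_out.sum())
    total = in_in + out_in + out_out
    if total > 0:
        shares = PatternShares(in_in / total, out_in / total, out_out / total)
    else:
        shares = PatternShares(0.0, 0.0, 0.0)

    annual_dose_ug = total * DAYS_PER_SEASON / 1000.0

    home_total = indoor_home.total @ tefs
    work_total = indoor_work.total @ tefs
    twa_by_season = (
        home_total * t_home + work_total * t_work + out_conc * t_out
    ) / HOURS_PER_DAY
    twa = float(twa_by_season.mean())

    return ExposureResult(
        annual_dose_ug=annual_dose_ug,
        time_weighted_conc_ng_m3=twa,
        lifetime_conc_ug_m3_year=lifetime_concentration(twa, lifetime_years),
        pattern_shares=shares,
        home_baepeq_ng_m3=float(home_total.mean()),
        outdoor_baepeq_ng_m3=float(out_conc.mean()),
    )


@dataclass(frozen=True)
class PatternSummary:
    """Population-level exposure-pattern statistics."""

    mean_shares: Mapping[str, float]
    dominance_rates: Mapping[str, float]   # pattern is the (unique) maximum
    over_half_rates: Mapping[str, float]   # pattern exceeds half the total


def _dominant_pattern(shares: PatternShares) -> str:
    m = max(shares)
    for name in _TIE_PRIORITY:
        if getattr(shares, name) == m:
            return name
    raise AssertionError("unreachable")


def pattern_statistics(
    results: Sequence[ExposureResult] | Iterable[ExposureResult],
) -> PatternSummary:
    """Mean shares, dominance rates and over-half rates across individuals.

    Dominance ties are broken by the fixed priority OUT_in > IN_in > OUT_out
    and each individual is counted exactly once.
    """
    results = list(results)
    if not results:
        raise ValueError("pattern statistics require a non-empty result list")
    n = len(results)
    shares = np.array([r.pattern_shares for r in results])  # (n, 3) IN_in,OUT_in,OUT_out
    mean_shares = dict(zip(PATTERNS, shares.mean(axis=0)))
    dom_counts = {p: 0 for p in PATTERNS}
    for r in results:
        dom_counts[_dominant_pattern(r.pattern_shares)] += 1
    dominance = {p: dom_counts[p] / n for p in PATTERNS}
    over_half = dict(zip(PATTERNS, (shares > 0.5).mean(axis=0)))
    return PatternSummary(
        mean_shares=mean_shares,
        dominance_rates=dominance,
        over_half_rates={k: float(v) for k, v in over_half.items()},
    )
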