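"""Scenario registry and the primitive edits, under common random numbers."""

import numpy as np
import pytest

from pahexposure.engine import run_scenario, sample_cohort
from pahexposure.scenarios import (
    apply_scenario,
    get_scenario,
    scenario_registry,
    who_target_baepeq,
)

ALL_IDS = {
    "B-u", "B-r", "SF-u", "SF-r", "CF-Hf-r", "CF-All-r", "Atm-Hf-u",
    "Atm-WHO-u", "Atm-WHO-r", "Ex-u", "Ex-80-r", "Ex-50-r", "Ex-20-r",
    "IC-u", "IC-r",
}


def test_registry_holds_the_fifteen_scenarios():
    registry = scenario_registry()
    assert len(registry) == 15
    assert {s.id for s in registry} == ALL_IDS
    assert all(s.id.endswith("-r") == (s.sub_population == "rural")
               for s in registry if s.id != "B-r")
    assert get_scenario("Atm-WHO-r").sub_population == "rural"
    assert get_scenario("Ex-20-r").sub_population == "rural"


def test_unknown_scenario_lists_valid_ids():
    with pytest.raises(ValueError, match="Atm-WHO-r"):
        get_scenario("Atm-WHO-x")


def test_who_target_division():
    assert who_target_baepeq(1.2, 0.381) == pytest.approx(3.1496, abs=1e-4)
    assert who_target_baepeq(2.5, 1.0) == 2.5
    assert who_target_baepeq(0.0, 0.381) == 0.0
    with pytest.raises(ValueError):
        who_target_baepeq(1.2, 0.0)


@pytest.fixture(scope="module")
def rural_cohort(default_settings):
    return sample_cohort(default_settings, "rural", 200, seed=31)


def _tefs(settings):
    return settings.congener_table.tefs


def test_baseline_identity(default_settings, rural_cohort):
    ind, fld = rural_cohort.individuals[0], rural_cohort.outdoor_fields[0]
    ind2, fld2 = apply_scenario(get_scenario("B-r"), ind, fld,
                                _tefs(default_settings))
    assert ind2 is ind and fld2 is fld


def test_atm_half_halves_every_congener_paired(default_settings, rural_cohort):
    scenario = get_scenario("Atm-Hf-u")  # sub-population checked in engine
    for ind, fld in zip(rural_cohort.individuals[:20],
                        rural_cohort.outdoor_fields[:20]):
        _, fld2 = apply_scenario(scenario, ind, fld, _tefs(default_settings))
        np.testing.assert_allclose(fld2.conc, 0.5 * fld.conc)


def test_atm_who_hits_target_exactly_per_season(default_settings, rural_cohort):
    scenario = get_scenario("Atm-WHO-r")
    target = who_target_baepeq(1.2, 0.381)
    tefs = _tefs(default_settings)
    for ind, fld in zip(rural_cohort.individuals[:20],
                        rural_cohort.outdoor_fields[:20]):
        _, fld2 = apply_scenario(scenario, ind, fld, tefs)
        np.testing.assert_allclose(fld2.baepeq_by_season(tefs), target,
                                   rtol=1e-12)


def test_ic_adds_time_averaged_cadr(default_settings, rural_cohort):
    # CADR 134 m3/h for 16 h/day -> 89.333 m3/h time-averaged
    scenario = get_scenario("IC-r")
    ind, fld = rural_cohort.individuals[0], rural_cohort.outdoor_fields[0]
    ind2, _ = apply_scenario(scenario, ind, fld, _tefs(default_settings))
    assert ind2.household.cadr == pytest.approx(134 * 16 / 24, abs=1e-9)
    assert ind.household.cadr == 0.0  # input untouched


def test_sf_differs_only_through_smoking(default_settings, rural_cohort):
    scenario = get_scenario("SF-r")
    for ind, fld in zip(rural_cohort.individuals[:50],
                        rural_cohort.outdoor_fields[:50]):
        ind2, fld2 = apply_scenario(scenario, ind, fld,
                                    _tefs(default_settings))
        assert ind2.household.smoking_cigarettes_per_day == 0.0
        assert ind2.workplace.smoking_cigarettes_per_day == 0.0
        np.testing.assert_array_equal(fld2.conc, fld.conc)
        assert ind2.household.fuel_use == ind.household.fuel_use
        assert ind2.household.ach == ind.household.ach
        assert ind2.time_budget == ind.time_budget


def test_erf_cap_never_raises_an_erf(default_settings, rural_cohort):
    scenario = get_scenario("Ex-80-r")
    for ind, fld in zip(rural_cohort.individuals[:50],
                        rural_cohort.outdoor_fields[:50]):
        ind2, _ = apply_scenario(scenario, ind, fld, _tefs(default_settings))
        for fuel, erf in ind2.household.fuel_erf.items():
            assert erf <= ind.household.fuel_erf[fuel] + 1e-12
            assert erf <= 0.8 + 1e-12


def test_fuel_shift_energy_equivalent_lpg(default_settings, rural_cohort):
    scenario = get_scenario("CF-All-r")
    energy = default_settings.fuel_energy_mj_per_kg
    shifted = 0
    for ind, fld in zip(rural_cohort.individuals,
                        rural_cohort.outdoor_fields):
        solid = (ind.household.fuel_use["wood_crop"]
                 + ind.household.fuel_use["coal"])
        ind2, _ = apply_scenario(scenario, ind, fld, _tefs(default_settings),
                                 default_settings.fuel_energy_mj_per_kg)
        if solid > 0:
            shifted += 1
            assert ind2.household.fuel_use["wood_crop"] == 0.0
            assert ind2.household.fuel_use["coal"] == 0.0
            expected_lpg = (
                ind.household.fuel_use["lpg"]
                + (ind.household.fuel_use["wood_crop"] * energy["wood_crop"]
                   + ind.household.fuel_use["coal"] * energy["coal"])
                / energy["lpg"]
            )
            assert ind2.household.fuel_use["lpg"] == pytest.approx(expected_lpg)
    assert shifted > 0


def test_fuel_shift_half_selects_about_half(default_settings):
    cohort = sample_cohort(default_settings, "rural", 2000, seed=37)
    scenario = get_scenario("CF-Hf-r")
    kept = shifted = 0
    for ind, fld in zip(cohort.individuals, cohort.outdoor_fields):
        if ind.household.fuel_use["wood_crop"] + ind.household.fuel_use["coal"] == 0:
            continue
        ind2, _ = apply_scenario(scenario, ind, fld,
                                 _tefs(default_settings))
        if ind2.household.fuel_use["wood_crop"] == 0:
            shifted += 1
        else:
            kept += 1
    frac = shifted / (shifted + kept)
    assert 0.45 < frac < 0.55


def test_exhaust_strength_ordering_under_crn(default_settings):
    """Mean indoor B[a]Peq: Ex-20 <= Ex-50 <= Ex-80 <= baseline."""
    cohort = sample_cohort(default_settings, "rural", 500, seed=41)
    means = {}
    for sid in ("Ex-20-r", "Ex-50-r", "Ex-80-r", "B-r"):
        summary = run_scenario(default_settings, sid, cohort=cohort)
        means[sid] = summary.home_baepeq.mean
    assert (means["Ex-20-r"] <= means["Ex-50-r"] <= means["Ex-80-r"]
            <= means["B-r"])
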