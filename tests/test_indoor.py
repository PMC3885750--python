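"""Single-zone steady state: closed form, additivity, monotonicity, ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from pahexposure.constants import N_CONGENERS
from pahexposure.indoor import (
    EmissionInventory,
    build_emission_inventory,
    io_ratio,
    steady_state_concentration,
)
from pahexposure.population import HouseholdEnv


def _env(**kw):
    base = dict(
        floor_area=50.0, ceiling_height=2.0, ach=0.5, penetration=0.9,
        deposition_rate_particle=0.2, cadr=0.0,
    )
    base.update(kw)
    return HouseholdEnv(**base)


def _mono(c16, value, index=0):
    arr = np.zeros(c16)
    arr[index] = value
    return arr


def test_no_source_unit_penetration_gives_io_of_one():
    env = _env(penetration=1.0, deposition_rate_particle=0.0)
    c_out = _mono(N_CONGENERS, 10.0)
    conc = steady_state_concentration(env, c_out, c_out, EmissionInventory.zero())
    np.testing.assert_allclose(conc.total, 2 * c_out)
    assert io_ratio(conc.total[0], 2 * c_out[0]) == pytest.approx(1.0)


def test_particle_infiltration_hand_arithmetic():
    # P=0.9, a=0.5/h, C_out=10, k=0.2/h -> 0.9*0.5*10/0.7 = 6.4286 ng/m3
    env = _env(ach=0.5, penetration=0.9, deposition_rate_particle=0.2)
    c_out_part = _mono(N_CONGENERS, 10.0)
    conc = steady_state_concentration(
        env, np.zeros(N_CONGENERS), c_out_part, EmissionInventory.zero()
    )
    assert conc.particle_outdoor[0] == pytest.approx(6.428571, abs=1e-5)


def test_indoor_emission_hand_arithmetic():
    # add E=1000 ng/h into V=100 m3: indoor-origin 10/0.7 = 14.286,
    # total 6.4286 + 14.286 = 20.714 ng/m3
    env = _env(floor_area=50.0, ceiling_height=2.0)  # V = 100
    inv = EmissionInventory(
        gas=np.zeros(N_CONGENERS), particle=_mono(N_CONGENERS, 1000.0)
    )
    c_out_part = _mono(N_CONGENERS, 10.0)
    conc = steady_state_concentration(env, np.zeros(N_CONGENERS), c_out_part, inv)
    assert conc.particle_indoor[0] == pytest.approx(14.285714, abs=1e-5)
    assert conc.total[0] == pytest.approx(20.714286, abs=1e-5)


def test_gas_phase_outdoor_origin_equals_outdoor():
    # gas: P = 1, k = 0, no cleaner effect -> indoor outdoor-origin == outdoor
    env = _env(cadr=500.0)
    c_gas = np.linspace(1, 16, N_CONGENERS)
    conc = steady_state_concentration(
        env, c_gas, np.zeros(N_CONGENERS), EmissionInventory.zero()
    )
    np.testing.assert_allclose(conc.gas_outdoor, c_gas)


def test_unventilated_household_rejected():
    env = _env(ach=0.0)
    with pytest.raises(ValueError, match="ventilation"):
        steady_state_concentration(
            env, np.zeros(N_CONGENERS), np.zeros(N_CONGENERS),
            EmissionInventory.zero(),
        )


def test_additivity_exact(default_settings):
    rng = np.random.default_rng(5)
    for _ in range(20):
        env = _env(ach=rng.uniform(0.1, 2), cadr=rng.uniform(0, 100))
        inv = EmissionInventory(
            gas=rng.uniform(0, 50, N_CONGENERS),
            particle=rng.uniform(0, 50, N_CONGENERS),
        )
        conc = steady_state_concentration(
            env, rng.uniform(0, 20, N_CONGENERS),
            rng.uniform(0, 20, N_CONGENERS), inv,
        )
        np.testing.assert_array_equal(
            conc.total, conc.outdoor_origin + conc.indoor_origin
        )


@given(
    cadr=st.floats(0.0, 300.0),
    k=st.floats(0.0, 2.0),
    e=st.floats(0.0, 5000.0),
    c_out=st.floats(0.0, 100.0),
)
def test_monotonicity_in_sinks_and_sources(cadr, k, e, c_out):
    """Indoor concentration falls with cadr and k, rises with E and C_out."""
    def total(cadr_, k_, e_, c_out_):
        env = _env(cadr=cadr_, deposition_rate_particle=k_)
        inv = EmissionInventory(
            gas=np.zeros(N_CONGENERS), particle=_mono(N_CONGENERS, e_)
        )
        conc = steady_state_concentration(
            env, np.zeros(N_CONGENERS), _mono(N_CONGENERS, c_out_), inv
        )
        return conc.total[0]

    base = total(cadr, k, e, c_out)
    assert total(cadr + 10, k, e, c_out) <= base + 1e-9
    assert total(cadr, k + 0.1, e, c_out) <= base + 1e-9
    assert total(cadr, k, e + 100, c_out) >= base - 1e-9
    assert total(cadr, k, e, c_out + 1) >= base - 1e-9


def test_steady_state_agrees_with_ode_time_stepping():
    """Independent oracle: integrate dC/dt = P*a*C_out + E/V - loss*C."""
    rng = np.random.default_rng(6)
    for _ in range(25):
        a = rng.uniform(0.1, 2.0)
        k = rng.uniform(0.0, 1.0)
        P = rng.uniform(0.3, 1.0)
        V = rng.uniform(30, 400)
        cadr = rng.uniform(0, 150)
        E = rng.uniform(0, 3000)
        c_out = rng.uniform(0, 50)
        loss = a + k + cadr / V

        def rhs(t, y):
            return [P * a * c_out + E / V - loss * y[0]]

        sol = solve_ivp(rhs, (0.0, 30.0 / loss), [0.0], rtol=1e-9, atol=1e-12)
        env = HouseholdEnv(
            floor_area=V / 2.7, ceiling_height=2.7, ach=a, penetration=P,
            deposition_rate_particle=k, cadr=cadr,
        )
        inv = EmissionInventory(
            gas=np.zeros(N_CONGENERS), particle=_mono(N_CONGENERS, E)
        )
        conc = steady_state_concentration(
            env, np.zeros(N_CONGENERS), _mono(N_CONGENERS, c_out), inv
        )
        assert conc.total[0] == pytest.approx(sol.y[0, -1], rel=1e-3, abs=1e-9)


def test_emission_inventory_rural_coal_arithmetic(default_settings):
    # 2 kg/day coal with chimney ERF 0.10: E = 2 * EF * 0.10 / 24 ng/h
    ef = default_settings.emission_factors
    env = _env()
    env.fuel_use = {"coal": 2.0}
    env.fuel_erf = {"coal": 0.10}
    inv = build_emission_inventory(env, ef)
    expected = 2.0 * (ef.phase("coal", "gas") + ef.phase("coal", "particle")) * 0.10 / 24.0
    np.testing.assert_allclose(inv.total, expected)


def test_emission_inventory_empty_household(default_settings):
    inv = build_emission_inventory(_env(), default_settings.emission_factors)
    assert np.all(inv.total == 0)


def test_remove_smoking_flag_zeroes_smoking_only(default_settings):
    env = _env()
    env.smoking_cigarettes_per_day = 10.0
    env.fuel_use = {"lpg": 0.5}
    env.fuel_erf = {"lpg": 1.0}
    with_smoke = build_emission_inventory(env, default_settings.emission_factors)
    without = build_emission_inventory(
        env, default_settings.emission_factors, remove_smoking=True
    )
    assert "smoking" not in without.by_source
    np.testing.assert_allclose(
        without.total, with_smoke.by_source["cooking_lpg"]["gas"]
        + with_smoke.by_source["cooking_lpg"]["particle"],
    )


def test_unknown_fuel_named_in_error(default_settings):
    env = _env()
    env.fuel_use = {"peat": 1.0}
    with pytest.raises(KeyError, match="peat"):
        build_emission_inventory(env, default_settings.emission_factors)


def test_io_ratio_zero_outdoor_flagged():
    with pytest.raises(ValueError, match="undefined"):
        io_ratio(1.0, 0.0)
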