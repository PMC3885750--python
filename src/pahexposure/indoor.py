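"""Steady-state indoor PAH concentrations from a single-zone mass balance.

The indoor air of each residence (and workplace) is treated as one
well-mixed zone at linear instantaneous equilibrium.  Per congener and per
phase p (gas / particle) the steady state of

    dC/dt = P_p * a * C_out,p + E_p / V - loss_p * C

is

    C = [P_p * a * C_out,p + E_p / V] / loss_p,
    loss_p = a + k_p + CADR_p / V,

with infiltration air-exchange rate ``a`` (1/h), penetration coefficient
``P`` (gas phase: P = 1), particle deposition rate ``k`` (gas phase: k = 0),
room volume ``V`` and a time-averaged clean-air delivery rate ``CADR``
acting on the particle phase only.  The two steady-state terms are kept
separate as the *outdoor-origin* and *indoor-origin* components, whose sum
is the total by construction; this split drives the IN-in / OUT-in / OUT-out
exposure-pattern decomposition downstream.

Indoor emissions (smoking, cooking fuel) are 24-h-averaged rates, ng/h, per
congener.  Emission factors are supplied as an editable table of ng per
cigarette and ng per kg of fuel; the packaged defaults are documented
assumptions, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .constants import HOURS_PER_DAY, N_CONGENERS
from .population import HouseholdEnv

__all__ = [
    "EmissionFactorTable",
    "EmissionInventory",
    "IndoorConc",
    "build_emission_inventory",
    "steady_state_concentration",
    "io_ratio",
]

#: emission-factor source key for tobacco smoke (unit = one cigarette)
SMOKING_SOURCE = "cigarette"


@dataclass
class EmissionFactorTable:
    """Per-source, per-phase, per-congener emission factors (ng per unit).

    ``sources`` maps a source name ("cigarette", "wood_crop", "coal",
    "lpg", ...) to ``{"gas": (16,), "particle": (16,)}`` arrays.  The unit is
    one cigarette for smoking and one kg for fuels.
    """

    sources: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        for source, phases in self.sources.items():
            for phase in ("gas", "particle"):
                if phase not in phases:
                    raise ValueError(f"source {source!r} lacks phase {phase!r}")
                arr = np.asarray(phases[phase], dtype=float)
                if arr.shape != (N_CONGENERS,):
                    raise ValueError(
                        f"emission factors for {source!r}/{phase} must have "
                        f"shape ({N_CONGENERS},)"
                    )
                if np.any(arr < 0):
                    raise ValueError(f"emission factors for {source!r} must be >= 0")
                phases[phase] = arr

    def __contains__(self, source: str) -> bool:
        return source in self.sources

    def phase(self, source: str, phase: str) -> np.ndarray:
        return self.sources[source][phase]

    def zeroed(self) -> "EmissionFactorTable":
        return EmissionFactorTable(
            sources={
                s: {p: np.zeros(N_CONGENERS) for p in ("gas", "particle")}
                for s in self.sources
            }
        )


@dataclass
class EmissionInventory:
    """24-h-averaged indoor emission rates, ng/h, per congener and phase."""

    gas: np.ndarray       # (16,)
    particle: np.ndarray  # (16,)
    by_source: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.gas + self.particle

    @classmethod
    def zero(cls) -> "EmissionInventory":
        return cls(gas=np.zeros(N_CONGENERS), particle=np.zeros(N_CONGENERS))


def build_emission_inventory(
    household: HouseholdEnv,
    ef_table: EmissionFactorTable,
    remove_smoking: bool = False,
) -> EmissionInventory:
    """Assemble the household's 24-h-averaged emission inventory.

    Per congener: ``E = (cigarettes/day * EF_cig
    + sum_fuel kg/day * EF_fuel * ERF_fuel) / 24`` where the
    emission-remaining factor ERF reflects exhaust measures (chimney, hood)
    and is 1 when everything stays indoors.  ``remove_smoking`` zeroes the
    smoking component only (fuel components unchanged).
    """
    gas = np.zeros(N_CONGENERS)
    particle = np.zeros(N_CONGENERS)
    by_source: dict[str, dict[str, np.ndarray]] = {}

    cigs = 0.0 if remove_smoking else household.smoking_cigarettes_per_day
    if cigs > 0:
        if SMOKING_SOURCE not in ef_table:
            raise KeyError(f"emission-factor table lacks source {SMOKING_SOURCE!r}")
        contrib = {
            p: cigs * ef_table.phase(SMOKING_SOURCE, p) / HOURS_PER_DAY
            for p in ("gas", "particle")
        }
        by_source["smoking"] = contrib
        gas += contrib["gas"]
        particle += contrib["particle"]

    for fuel, kg_per_day in household.fuel_use.items():
        if kg_per_day == 0:
            continue
        if fuel not in ef_table:
            raise KeyError(f"no emission factors for fuel {fuel!r}")
        erf = household.fuel_erf.get(fuel, 1.0)
        contrib = {
            p: kg_per_day * ef_table.phase(fuel, p) * erf / HOURS_PER_DAY
            for p in ("gas", "particle")
        }
        by_source[f"cooking_{fuel}"] = contrib
        gas += contrib["gas"]
        particle += contrib["particle"]

    return EmissionInventory(gas=gas, particle=particle, by_source=by_source)


@dataclass
class IndoorConc:
    """Indoor concentrations split by phase and origin, ng/m3.

    All arrays share one shape, either ``(n_congeners,)`` or
    ``(n_seasons, n_congeners)``.  ``total == outdoor_origin +
    indoor_origin`` holds exactly, per congener and per phase.
    """

    gas_outdoor: np.ndarray
    gas_indoor: np.ndarray
    particle_outdoor: np.ndarray
    particle_indoor: np.ndarray

    @property
    def outdoor_origin(self) -> np.ndarray:
        return self.gas_outdoor + self.particle_outdoor

    @property
    def indoor_origin(self) -> np.ndarray:
        return self.gas_indoor + self.particle_indoor

    @property
    def total(self) -> np.ndarray:
        return self.outdoor_origin + self.indoor_origin

    @property
    def gas(self) -> np.ndarray:
        return self.gas_outdoor + self.gas_indoor

    @property
    def particle(self) -> np.ndarray:
        return self.particle_outdoor + self.particle_indoor

    def baepeq(self, tefs: np.ndarray) -> np.ndarray:
        return self.total @ tefs


def steady_state_concentration(
    env: HouseholdEnv,
    c_out_gas: np.ndarray,
    c_out_particle: np.ndarray,
    emissions: EmissionInventory,
) -> IndoorConc:
    """Closed-form single-zone steady state, per phase and origin.

    Gas phase: penetration 1, no deposition, no cleaner effect (a particle
    cleaner has no direct effect on the gas phase), so the outdoor-origin
    gas concentration equals the outdoor gas concentration exactly.
    Particle phase: loss = a + k + CADR/V.  Outdoor concentration arrays may
    be ``(16,)`` or ``(4, 16)``; emissions are season-constant.
    """
    a = env.ach
    if a <= 0:
        raise ValueError(
            "household has no ventilation (air-exchange rate <= 0); the "
            "steady state is undefined"
        )
    V = env.volume
    c_out_gas = np.asarray(c_out_gas, dtype=float)
    c_out_particle = np.asarray(c_out_particle, dtype=float)

    loss_gas = a
    loss_particle = a + env.deposition_rate_particle + env.cadr / V
    gas_outdoor = a * c_out_gas / loss_gas
    gas_indoor = np.broadcast_to(
        (emissions.gas / V) / loss_gas, c_out_gas.shape
    ).copy()
    particle_outdoor = env.penetration * a * c_out_particle / loss_particle
    particle_indoor = np.broadcast_to(
        (emissions.particle / V) / loss_particle, c_out_particle.shape
    ).copy()
    return IndoorConc(
        gas_outdoor=gas_outdoor,
        gas_indoor=gas_indoor,
        particle_outdoor=particle_outdoor,
        particle_indoor=particle_indoor,
    )


def io_ratio(indoor_baepeq: float, outdoor_baepeq: float) -> float:
    """Indoor/outdoor B[a]Peq concentration ratio; > 1 flags indoor sources."""
    if outdoor_baepeq <= 0:
        raise ValueError(
            "I/O ratio undefined: outdoor B[a]Peq concentration is zero"
        )
    return indoor_baepeq / outdoor_baepeq
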