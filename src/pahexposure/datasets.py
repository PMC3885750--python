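"""Loaders for the packaged input tables and the default configuration.

Packaged data:

* ``outdoor_concentrations.csv`` — seasonal outdoor medians and SDs for the
  16 congeners (Beijing, 2005–2007 measurement summaries);
* ``tefs.csv`` — toxic equivalency factors (Nisbet & LaGoy scheme,
  TEF(BaP) = 1);
* ``particle_fractions.csv`` — assumed particle-bound fraction per congener
  (1 for the 5+-ring congeners, 0.5 for chrysene/benz[a]anthracene, 0.05
  for the lighter congeners);
* ``emission_factors.csv`` — per-cigarette and per-kg-fuel emission factors.
  These are *placeholder assumptions* (no values are published alongside
  the concentration table) whose magnitudes were chosen to reproduce the
  reported relative importance of indoor sources; treat them as editable
  defaults, not measurements;
* ``default_config.yaml`` — demographics, per-region parameter
  distributions and physical defaults for the Beijing 2006 population.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .config import Settings
from .constants import CONGENERS, N_CONGENERS, SEASONS
from .indoor import EmissionFactorTable
from .outdoor import CongenerTable
from .population import (
    BreathingParams,
    ParamSpec,
    PopulationConfig,
    RegionParams,
    WorkplaceParams,
)
from .risk import RiskConfig

__all__ = [
    "data_path",
    "load_congener_table",
    "load_emission_factors",
    "load_default_settings",
]

_PARAM_KEYS = (
    "ach", "floor_area_m2", "penetration", "time_home_h",
    "time_work_school_h", "smoking_cigs_per_day",
    "wood_crop_kg_day", "coal_kg_day", "lpg_kg_day",
)
_FRACTION_KEYS = (
    "coal_user_fraction", "hood_user_fraction",
    "home_smoking_ban_fraction", "workplace_smoking_ban_fraction",
)


def data_path(name: str) -> Path:
    return Path(str(files("pahexposure").joinpath("data", name)))


def _congener_series(df: pd.DataFrame, value_col: str, key: str) -> np.ndarray:
    got = set(df["congener"])
    missing = [c for c in CONGENERS if c not in got]
    if missing:
        raise ValueError(f"{key}: missing congener(s) {missing}")
    s = df.set_index("congener")[value_col]
    return np.array([float(s[c]) for c in CONGENERS])


def load_congener_table(
    outdoor_csv: Path | None = None,
    tef_csv: Path | None = None,
    particle_fraction_csv: Path | None = None,
) -> CongenerTable:
    """Assemble the outdoor concentration table from its three CSVs."""
    outdoor = pd.read_csv(outdoor_csv or data_path("outdoor_concentrations.csv"))
    tefs = pd.read_csv(tef_csv or data_path("tefs.csv"))
    pf = pd.read_csv(particle_fraction_csv or data_path("particle_fractions.csv"))

    medians = np.zeros((len(SEASONS), N_CONGENERS))
    sds = np.zeros_like(medians)
    for si, season in enumerate(SEASONS):
        block = outdoor[outdoor["season"] == season]
        if block.empty:
            raise ValueError(f"outdoor table lacks season {season!r}")
        medians[si] = _congener_series(block, "median_ng_m3", f"outdoor[{season}]")
        sds[si] = _congener_series(block, "sd_ng_m3", f"outdoor[{season}]")
    return CongenerTable(
        medians=medians,
        sds=sds,
        tefs=_congener_series(tefs, "tef", "tefs"),
        particle_fraction=_congener_series(pf, "particle_fraction", "particle_fractions"),
    )


def load_emission_factors(csv: Path | None = None) -> EmissionFactorTable:
    df = pd.read_csv(csv or data_path("emission_factors.csv"))
    sources: dict[str, dict[str, np.ndarray]] = {}
    for (source, phase), block in df.groupby(["source", "phase"]):
        arr = _congener_series(block, "ng_per_unit", f"emission_factors[{source}/{phase}]")
        sources.setdefault(source, {})[phase] = arr
    for source, phases in sources.items():
        for p in ("gas", "particle"):
            phases.setdefault(p, np.zeros(N_CONGENERS))
    return EmissionFactorTable(sources=sources)


def _param_spec(raw: Any, key: str) -> ParamSpec:
    if not isinstance(raw, dict) or "mean" not in raw:
        raise ValueError(f"{key} must be a mapping with at least a 'mean' entry")
    spec = ParamSpec(
        mean=float(raw["mean"]),
        sd=float(raw.get("sd", 0.0)),
        family=str(raw.get("family", "truncnorm")),
        low=float(raw.get("low", 0.0)),
        high=float(raw.get("high", np.inf)),
    )
    spec.validate(key)
    return spec


def _region_params(raw: dict, key: str) -> RegionParams:
    kwargs: dict[str, Any] = {}
    for name in _PARAM_KEYS:
        if name not in raw:
            raise ValueError(f"{key}.{name} is required")
        kwargs[name] = _param_spec(raw[name], f"{key}.{name}")
    for name in _FRACTION_KEYS:
        v = float(raw.get(name, 0.0))
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{key}.{name} must be a proportion in [0, 1] (got {v})")
        kwargs[name] = v
    return RegionParams(**kwargs)


def population_config_from_dict(raw: dict) -> PopulationConfig:
    """Build and validate a population config from a parsed YAML mapping."""
    try:
        regions_raw = raw["regions"]
    except KeyError as exc:
        raise ValueError("population.regions is required") from exc
    regions = {
        name: _region_params(block, f"population.regions.{name}")
        for name, block in regions_raw.items()
    }
    wp = raw.get("workplace", {})
    breathing = raw.get("breathing", {})
    cfg = PopulationConfig(
        urban_fraction=float(raw["urban_fraction"]),
        male_fraction=float(raw.get("male_fraction", 0.5)),
        smoker_fraction=float(raw["smoker_fraction"]),
        employed_fraction=float(raw["employed_fraction"]),
        school_age_fraction=float(raw.get("school_age_fraction", 0.0)),
        regions=regions,
        workplace=WorkplaceParams(
            ach=float(wp.get("ach", 1.0)),
            volume_m3=float(wp.get("volume_m3", 30.0)),
            penetration=float(wp.get("penetration", 0.9)),
        ),
        breathing=BreathingParams(
            daily_volume_m3=float(breathing.get("daily_volume_m3", 16.0)),
            multipliers=dict(
                breathing.get("multipliers", {"home": 0.8, "work": 1.0, "outdoor": 1.5})
            ),
        ),
        ceiling_height_m=float(raw.get("ceiling_height_m", 2.7)),
        deposition_rate_particle=float(raw.get("deposition_rate_particle", 0.2)),
        erf_chimney=float(raw.get("erf_chimney", 0.10)),
        erf_hood=float(raw.get("erf_hood", 0.50)),
    )
    cfg.validate()
    return cfg


def settings_from_dict(raw: dict) -> Settings:
    """Assemble full settings from a parsed YAML mapping (paths resolved)."""
    population = population_config_from_dict(raw["population"])
    paths = raw.get("paths", {})

    def _p(key: str) -> Path | None:
        return Path(paths[key]) if key in paths else None

    table = load_congener_table(
        outdoor_csv=_p("outdoor_concentrations"),
        tef_csv=_p("tefs"),
        particle_fraction_csv=_p("particle_fractions"),
    )
    efs = load_emission_factors(_p("emission_factors"))
    risk_raw = raw.get("risk", {})
    cleaner = raw.get("cleaner", {})
    who = raw.get("who", {})
    settings = Settings(
        population=population,
        congener_table=table,
        emission_factors=efs,
        risk=RiskConfig(
            urr=float(risk_raw.get("urr", 4.49)),
            urr_alternative=float(risk_raw.get("urr_alternative", 1.30)),
            reference_exposure=float(risk_raw.get("reference_exposure", 100.0)),
        ),
        cleaner_cadr_m3_h=float(cleaner.get("cadr_m3_h", 134.0)),
        cleaner_hours_per_day=float(cleaner.get("hours_per_day", 16.0)),
        who_bap_guideline_ng_m3=float(who.get("bap_guideline_ng_m3", 1.2)),
        who_bap_fraction=float(who.get("bap_fraction_of_baepeq", 0.381)),
        fuel_energy_mj_per_kg=dict(
            raw.get("fuel_energy_mj_per_kg",
                    {"wood_crop": 16.0, "coal": 23.0, "lpg": 46.0})
        ),
        correlated_outdoor=bool(raw.get("correlated_outdoor", True)),
        lifetime_years=float(raw.get("lifetime_years", 70.0)),
    )
    settings.validate()
    return settings


def load_default_settings() -> Settings:
    """Packaged defaults: Beijing 2006 demographics and parameter tables."""
    with open(data_path("default_config.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return settings_from_dict(raw)
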