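"""Configuration loading/validation and report generation.

Reports are plain CSV/JSON with fixed column order and documented units so
that a run manifest plus a seed fully determines every output byte.
Percent-valued columns are written both rounded to two decimals (matching
the precision risk tables are usually printed at) and at full precision in
a parallel ``*_full`` column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .config import Settings
from .constants import PATTERNS
from .datasets import data_path, settings_from_dict
from .engine import ComparisonResult, ScenarioSummary, SensitivityResult

__all__ = ["load_and_validate", "write_reports"]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_and_validate(config_path: str | Path | None = None) -> Settings:
    """Load settings; a user YAML overrides the packaged defaults key-wise.

    Validation happens before any simulation starts and errors name the
    offending key and constraint.
    """
    with open(data_path("default_config.yaml")) as fh:
        raw = yaml.safe_load(fh)
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        raw = _deep_merge(raw, user)
    return settings_from_dict(raw)


def _settings_digest(settings: Settings) -> str:
    payload = {
        "population": repr(settings.population),
        "medians": settings.congener_table.medians.tolist(),
        "sds": settings.congener_table.sds.tolist(),
        "tefs": settings.congener_table.tefs.tolist(),
        "particle_fraction": settings.congener_table.particle_fraction.tolist(),
        "emission_factors": {
            s: {p: arr.tolist() for p, arr in phases.items()}
            for s, phases in settings.emission_factors.sources.items()
        },
        "risk": repr(settings.risk),
        "cleaner": [settings.cleaner_cadr_m3_h, settings.cleaner_hours_per_day],
        "who": [settings.who_bap_guideline_ng_m3, settings.who_bap_fraction],
        "fuel_energy": dict(settings.fuel_energy_mj_per_kg),
        "correlated_outdoor": settings.correlated_outdoor,
        "lifetime_years": settings.lifetime_years,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _summary_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "scenario": s.scenario_id,
            "sub_population": s.sub_population,
            "n_reps": s.n_reps,
            "mean_rr": s.mean_rr,
            "paf_pct": round(100 * s.paf, 2),
            "paf_pct_full": 100 * s.paf,
        }
        for metric in ("home_baepeq", "io_ratio", "annual_dose"):
            stats = getattr(s, metric)
            for stat in ("mean", "p25", "p75", "p95"):
                row[f"{metric}_{stat}"] = getattr(stats, stat)
        for p in PATTERNS:
            row[f"mean_share_{p}"] = s.pattern.mean_shares[p]
            row[f"dominance_{p}"] = s.pattern.dominance_rates[p]
            row[f"over_half_{p}"] = s.pattern.over_half_rates[p]
        rows.append(row)
    return pd.DataFrame(rows)


def _ranking_frame(result: ComparisonResult) -> pd.DataFrame:
    frames = []
    for region in sorted(result.rankings):
        frames.append(result.rankings[region])
    table = pd.concat(frames, ignore_index=True)
    table["pif_pct"] = (100 * table["pif"]).round(2)
    table["pif_pct_full"] = 100 * table["pif"]
    table["paf_remaining_pct"] = (100 * table["paf_remaining"]).round(2)
    return table


def _risk_frame(result: ComparisonResult, settings: Settings) -> pd.DataFrame:
    table = result.risk_table(settings)
    table["paf_pct"] = (100 * table["paf"]).round(2)
    table["paf_pct_full"] = 100 * table["paf"]
    table["pif_pct"] = (100 * table["pif"]).round(2)
    table["pif_pct_full"] = 100 * table["pif"]
    return table


def _sensitivity_frame(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for sid, pct in sorted(r.pct_change_dose.items()):
            rows.append(
                {
                    "parameter": r.parameter,
                    "direction": r.direction,
                    "scenario": sid,
                    "pct_change_mean_annual_dose": pct,
                }
            )
    return pd.DataFrame(rows)


def _per_individual_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        if s.results is None:
            continue
        for r in s.results:
            rows.append(
                {
                    "scenario": s.scenario_id,
                    "region": s.sub_population,
                    "annual_dose_ug": r.annual_dose_ug,
                    "twa_conc_ng_m3": r.time_weighted_conc_ng_m3,
                    "c_life": r.lifetime_conc_ug_m3_year,
                    "share_in_in": r.pattern_shares.IN_in,
                    "share_out_in": r.pattern_shares.OUT_in,
                    "share_out_out": r.pattern_shares.OUT_out,
                }
            )
    return pd.DataFrame(rows)


def write_reports(
    outdir: str | Path,
    settings: Settings,
    comparison: ComparisonResult,
    sensitivity: Sequence[SensitivityResult] | None = None,
    per_individual: bool = False,
    plots: bool = False,
) -> dict[str, Path]:
    """Write scenario summaries, rankings, the URR risk table and a manifest.

    Returns the mapping of logical report name to written path.  A re-run
    from the same manifest (settings + seed + n_reps + scenario set)
    reproduces every CSV byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    summaries = [comparison.summaries[k] for k in sorted(comparison.summaries)]
    paths = {
        "scenario_summaries": outdir / "scenario_summaries.csv",
        "ranking": outdir / "ranking.csv",
        "table4": outdir / "table4.csv",
    }
    _summary_frame(summaries).to_csv(paths["scenario_summaries"], index=False)
    if comparison.rankings:
        _ranking_frame(comparison).to_csv(paths["ranking"], index=False)
        written["ranking"] = paths["ranking"]
    _risk_frame(comparison, settings).to_csv(paths["table4"], index=False)
    written["scenario_summaries"] = paths["scenario_summaries"]
    written["table4"] = paths["table4"]

    if sensitivity:
        sens_path = outdir / "sensitivity.csv"
        _sensitivity_frame(sensitivity).to_csv(sens_path, index=False)
        written["sensitivity"] = sens_path

    if per_individual:
        frame = _per_individual_frame(summaries)
        if not frame.empty:
            pi_path = outdir / "per_individual.csv"
            frame.to_csv(pi_path, index=False)
            written["per_individual"] = pi_path

    manifest = {
        "config_sha256": _settings_digest(settings),
        "seed": comparison.seed,
        "n_reps": comparison.n_reps,
        "scenarios": sorted(comparison.summaries),
        "baselines": comparison.baselines,
        "outputs": {k: p.name for k, p in written.items()},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path

    if plots:
        written.update(_write_plots(outdir, summaries))
    return written


def _write_plots(outdir: Path, summaries: Sequence[ScenarioSummary]) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    ids = [s.scenario_id for s in summaries]

    fig, ax = plt.subplots(figsize=(9, 4))
    means = [s.home_baepeq.mean for s in summaries]
    p25 = [s.home_baepeq.p25 for s in summaries]
    p75 = [s.home_baepeq.p75 for s in summaries]
    p95 = [s.home_baepeq.p95 for s in summaries]
    x = range(len(ids))
    ax.bar(x, means, color="0.6", label="mean")
    ax.vlines(x, p25, p75, color="k", lw=4, alpha=0.5, label="IQR")
    ax.scatter(x, p95, color="k", marker="o", s=12, label="P95")
    ax.set_xticks(list(x), ids, rotation=60, ha="right")
    ax.set_ylabel("home indoor B[a]Peq (ng/m3)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = outdir / "home_baepeq.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written["plot_home_baepeq"] = path

    fig, ax = plt.subplots(figsize=(9, 4))
    bottoms = [0.0] * len(ids)
    for pattern, color in zip(PATTERNS, ("0.2", "0.5", "0.8")):
        vals = [s.pattern.mean_shares[pattern] for s in summaries]
        ax.bar(x, vals, bottom=bottoms, color=color, label=pattern.replace("_", "-"))
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_xticks(list(x), ids, rotation=60, ha="right")
    ax.set_ylabel("mean exposure share")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = outdir / "pattern_shares.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written["plot_pattern_shares"] = path
    return written
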