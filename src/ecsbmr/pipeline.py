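"""End-to-end pipeline: covariate scan, combined fit, ES and 1SD BMR tables.

`run_pipeline` ties the stages together and writes deterministic, seed- and
config-stamped JSON/CSV artifacts:

1. covariate scan per experimental factor (``covariate_scan.json`` and the
   tidy box-plot points ``boxplot_data.csv``);
2. combined-fit ``var``/``c`` with 90% profile intervals and fitted curves
   on a dose grid (``fit.json``);
3. effect-size-theory BMR table, one row per technology;
4. one-SD BMR table (study-specific SD, truncated historical SD, MAD).

Identical configs (including the seed) produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmr_es, bmr_sd, covariates
from .dataio import StudyDatabase, extract_controls, read_database
from .errors import EcsbmrError
from .model import FitOptions, fit_combined, model_mean

logger = logging.getLogger("ecsbmr")

STAGES = ("covariates", "fit", "bmr_es", "bmr_sd")


@dataclass
class PipelineConfig:
    input_path: str | None = None
    technologies: list[str] | None = None  # default: all in the database
    stages: tuple[str, ...] = STAGES
    seed: int = 1
    n_starts: int = 3
    profile_c: bool = True
    factors: tuple[str, ...] = covariates.DEFAULT_FACTORS
    k: float = bmr_es.DEFAULT_K
    fraction: float = bmr_es.DEFAULT_FRACTION
    trim: float = 0.05
    mad_scale: bool = True
    aggregate: str = "median"
    out_dir: str = "ecsbmr_out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=True)


def _jsonify(x):
    if isinstance(x, float) and not np.isfinite(x):
        return "inf" if x > 0 else "-inf"
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonify(v) for k, v in x.items()}
    return x


def run_pipeline(config: PipelineConfig, db: StudyDatabase | None = None) -> dict:
    """Run the configured stages; returns ``{stage: output-path}``.

    A stage failure halts downstream stages and is recorded in a structured
    ``error.json`` report.
    """
    if db is None:
        if config.input_path is None:
            raise ValueError("either a database or config.input_path is required")
        db = read_database(config.input_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    technologies = config.technologies or db.technologies
    opts = FitOptions(
        seed=config.seed, n_starts=config.n_starts, profile_c=config.profile_c
    )
    artifacts: dict[str, str] = {}
    results: dict[str, dict] = {}

    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "covariates":
                payload = {**_stamp(config), "technologies": {}}
                frames = []
                for tech in technologies:
                    scans = covariates.scan_all(db, tech, config.factors, opts)
                    payload["technologies"][tech] = [
                        {
                            "factor": r.factor,
                            "overlap_flag": r.overlap_flag,
                            "error": r.error,
                            "levels": [
                                {
                                    "level": lv.level,
                                    "n_datasets": lv.n_datasets,
                                    "var": lv.var,
                                    "ci90_var": _jsonify(list(lv.ci90_var)),
                                    "low_information": lv.low_information,
                                }
                                for lv in r.levels
                            ],
                        }
                        for r in scans
                    ]
                    bp = covariates.export_boxplot_data(db, tech, scans, opts)
                    bp.insert(0, "technology", tech)
                    frames.append(bp)
                path = out / "covariate_scan.json"
                _dump_json(payload, path)
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "boxplot_data.csv", index=False
                )
                artifacts[stage] = str(path)
                results[stage] = payload
            elif stage == "fit":
                payload = {**_stamp(config), "technologies": {}}
                for tech in technologies:
                    sub = db.filter(tech)
                    if len(sub) == 0:
                        continue
                    fit = fit_combined(sub.datasets, opts)
                    curves = {}
                    for ds in sub:
                        params = fit.params_for(ds.dataset_id)
                        grid = np.linspace(0, ds.doses.max(), 25)
                        curves[ds.dataset_id] = {
                            "dose": grid.tolist(),
                            "mean": model_mean(params, grid).tolist(),
                        }
                    payload["technologies"][tech] = {
                        "n_datasets": len(sub),
                        "n_obs": fit.n_obs,
                        "var": fit.var,
                        "var_mle": fit.var_mle,
                        "ci90_var": _jsonify(list(fit.ci90_var)),
                        "c": fit.c,
                        "ci90_c": _jsonify(list(fit.ci90_c)) if fit.ci90_c else None,
                        "d": fit.d,
                        "loglik": fit.loglik,
                        "converged": fit.converged,
                        "per_dataset": {
                            k: {"a": a, "b": b} for k, (a, b) in fit.per_dataset.items()
                        },
                        "curves": curves,
                    }
                path = out / "fit.json"
                _dump_json(payload, path)
                artifacts[stage] = str(path)
                results[stage] = payload
            elif stage == "bmr_es":
                if "fit" not in results:
                    raise EcsbmrError("bmr_es stage requires the fit stage")
                rows = []
                for tech, f in results["fit"]["technologies"].items():
                    res = bmr_es.bmr_from_var(
                        f["var"], config.k, config.fraction, n_basis=f["n_datasets"]
                    )
                    lo, hi = bmr_es.bmr_interval_from_var_ci(
                        tuple(f["ci90_var"]), config.k, config.fraction
                    )
                    rows.append(
                        {
                            "technology": tech,
                            "n_datasets": f["n_datasets"],
                            "var": round(f["var"], 3),
                            "var_ci90_low": round(f["ci90_var"][0], 3),
                            "var_ci90_high": round(f["ci90_var"][1], 3),
                            "bmr_percent": res.percent,
                            "bmr_ci90_low_percent": round(100 * lo, 1),
                            "bmr_ci90_high_percent": round(100 * hi, 1),
                        }
                    )
                table = pd.DataFrame(
                    rows,
                    columns=[
                        "technology",
                        "n_datasets",
                        "var",
                        "var_ci90_low",
                        "var_ci90_high",
                        "bmr_percent",
                        "bmr_ci90_low_percent",
                        "bmr_ci90_high_percent",
                    ],
                )
                path = out / "bmr_es_table.csv"
                table.to_csv(path, index=False)
                _dump_json(
                    {**_stamp(config), "rows": rows}, out / "bmr_es_table.json"
                )
                artifacts[stage] = str(path)
                results[stage] = {"rows": rows}
            elif stage == "bmr_sd":
                rows = []
                for tech in technologies:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pooled = extract_controls(db, tech)
                    if pooled.size == 0:
                        continue
                    study = bmr_sd.bmr_study_specific(db, tech, config.aggregate)
                    hist = bmr_sd.bmr_historical_sd(pooled, config.trim)
                    mad = bmr_sd.bmr_historical_mad(pooled, config.mad_scale)
                    rows.append(
                        {
                            "technology": tech,
                            "n_studies": study.n_basis,
                            "bmr_study_specific_percent": study.percent,
                            "n_obs": hist.n_basis,
                            "bmr_historical_sd_percent": hist.percent,
                            "bmr_historical_mad_percent": mad.percent,
                        }
                    )
                table = pd.DataFrame(
                    rows,
                    columns=[
                        "technology",
                        "n_studies",
                        "bmr_study_specific_percent",
                        "n_obs",
                        "bmr_historical_sd_percent",
                        "bmr_historical_mad_percent",
                    ],
                )
                path = out / "bmr_sd_table.csv"
                table.to_csv(path, index=False)
                _dump_json(
                    {**_stamp(config), "rows": rows}, out / "bmr_sd_table.json"
                )
                artifacts[stage] = str(path)
                results[stage] = {"rows": rows}
            else:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        report = {
            **_stamp(config),
            "failed_stage": stage,
            "error": f"{type(exc).__name__}: {exc}",
            "completed_stages": sorted(artifacts),
        }
        _dump_json(report, out / "error.json")
        raise
    return artifacts


def render_tables(results: dict, out_dir) -> dict[str, str]:
    """Re-render the ES and 1SD BMR tables from in-memory stage results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stage, fname in (("bmr_es", "bmr_es_table.csv"), ("bmr_sd", "bmr_sd_table.csv")):
        rows = results.get(stage, {}).get("rows", [])
        pd.DataFrame(rows).to_csv(out / fname, index=False)
        paths[stage] = str(out / fname)
    return paths
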