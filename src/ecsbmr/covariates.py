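"""Experimental-factor influence on within-group variance.

Before pooling datasets into a single combined fit, the analysis asks
whether experimental factors (species, strain, administration route,
application time, tissue, sampling time, DNA fragmentation method)
influence the within-group variance ``var``.  Datasets are grouped by
factor level, a combined fit is run per level, and levels are judged
compatible when their 90% profile intervals all pairwise overlap — a
formalization of the visual box-plot comparison this style of analysis
normally relies on.  An optional likelihood-ratio diagnostic comparing a
shared-var model against level-specific var is provided, but the headline
flag is the CI-overlap rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import stats

from .dataio import StudyDatabase
from .errors import EcsbmrError
from .model import FitOptions, fit_combined, fit_single

#: The seven factors examined for the flagship technology.
DEFAULT_FACTORS = (
    "species",
    "strain",
    "route",
    "application_time_days",
    "tissue",
    "sampling_time_days",
    "fragmentation_method",
)


@dataclass
class LevelResult:
    level: str
    n_datasets: int
    var: float
    ci90_var: tuple[float, float]
    low_information: bool = False


@dataclass
class CovariateScanResult:
    factor: str
    levels: list[LevelResult] = field(default_factory=list)
    overlap_flag: bool = True
    lr_pvalue: float | None = None
    error: str | None = None

    @property
    def n_datasets(self) -> int:
        return sum(lv.n_datasets for lv in self.levels)


def _intervals_all_overlap(intervals: list[tuple[float, float]]) -> bool:
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            lo = max(intervals[i][0], intervals[j][0])
            hi = min(intervals[i][1], intervals[j][1])
            if lo > hi:
                return False
    return True


def scan_factor(
    db: StudyDatabase,
    technology: str,
    factor: str,
    opts: FitOptions | None = None,
    lr_test: bool = False,
) -> CovariateScanResult:
    """Estimate var per level of one factor and flag CI overlap across levels."""
    sub = db.filter(technology)
    available = sorted({k for ds in sub for k in ds.covariates})
    if factor not in available:
        raise EcsbmrError(
            f"unknown factor {factor!r}; available factors: {available}"
        )
    opts = opts or FitOptions()
    opts = replace(opts, profile_c=False)
    by_level: dict[str, list] = {}
    for ds in sub:
        if factor in ds.covariates:
            by_level.setdefault(str(ds.covariates[factor]), []).append(ds)

    levels, deviance_parts = [], []
    for level in sorted(by_level):
        datasets = by_level[level]
        fit = fit_combined(datasets, opts)
        levels.append(
            LevelResult(
                level=level,
                n_datasets=len(datasets),
                var=fit.var,
                ci90_var=fit.ci90_var,
                low_information=len(datasets) < 2,
            )
        )
        deviance_parts.append((fit.sse, fit.n_obs))

    overlap = _intervals_all_overlap([lv.ci90_var for lv in levels])
    result = CovariateScanResult(factor=factor, levels=levels, overlap_flag=overlap)
    if lr_test and len(levels) > 1:
        # shared-var vs level-specific-var, mean structure refit per level either way
        sse_tot = sum(s for s, _ in deviance_parts)
        n_tot = sum(n for _, n in deviance_parts)
        ll_shared = -0.5 * n_tot * (math.log(2 * math.pi * sse_tot / n_tot) + 1)
        ll_split = sum(
            -0.5 * n * (math.log(2 * math.pi * s / n) + 1)
            for s, n in deviance_parts
            if s > 0
        )
        lr = max(2 * (ll_split - ll_shared), 0.0)
        result.lr_pvalue = float(stats.chi2(df=len(levels) - 1).sf(lr))
    return result


def scan_all(
    db: StudyDatabase,
    technology: str,
    factors=DEFAULT_FACTORS,
    opts: FitOptions | None = None,
) -> list[CovariateScanResult]:
    """Map :func:`scan_factor` over a factor list; per-factor errors are
    captured in the result instead of aborting the batch."""
    results = []
    for factor in factors:
        try:
            results.append(scan_factor(db, technology, factor, opts))
        except EcsbmrError as exc:
            warnings.warn(f"factor {factor!r} skipped: {exc}")
            results.append(
                CovariateScanResult(factor=factor, levels=[], error=str(exc))
            )
    return results


def export_boxplot_data(
    db: StudyDatabase,
    technology: str,
    results: list[CovariateScanResult],
    opts: FitOptions | None = None,
) -> pd.DataFrame:
    """Tidy per-dataset var values by factor level (box-plot points).

    One row per (factor, level, dataset); the var of each point comes from
    a single-dataset fit, so aggregating rows by level reproduces the scan
    counts.
    """
    sub = db.filter(technology)
    opts = opts or FitOptions()
    opts = replace(opts, profile_c=False)
    single_var = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ds in sub:
            single_var[ds.dataset_id] = fit_single(ds, opts).var
    rows = []
    for res in results:
        if res.error:
            continue
        for ds in sub:
            level = ds.covariates.get(res.factor)
            if level is not None:
                rows.append(
                    {
                        "factor": res.factor,
                        "level": str(level),
                        "dataset_id": ds.dataset_id,
                        "var": single_var[ds.dataset_id],
                    }
                )
    return pd.DataFrame(rows, columns=["factor", "level", "dataset_id", "var"])
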