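"""One-standard-deviation benchmark responses from negative-control variability.

Following the Zeller-style 1SD approach, the benchmark response is the
relative change from control corresponding to one dispersion unit of the
negative-control distribution.  Three dispersion measures are supported:

* study-specific control SDs (``sd_study``): per-study coefficient of
  variation SD/mean, aggregated across studies (median by default);
* the SD of the pooled historical-control distribution after right-
  truncation of the uppermost 5% (``sd_hist_trunc``);
* the median absolute deviation of the pooled historical controls
  (``mad_hist``), consistency-scaled by 1.4826 by default and divided by
  the median.

All three are dimensionless ratios (dispersion over the matching location
measure), reported as fractional increases over control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bmr_es import BMRResult
from .dataio import StudyDatabase, extract_controls

#: Normal-consistency factor making the MAD comparable to an SD.
MAD_CONSISTENCY = 1.4826


@dataclass
class ControlStats:
    """Summary statistics of a negative-control observation pool."""

    n_obs: int
    mean: float
    sd: float
    trimmed_n: int
    trimmed_mean: float
    trimmed_sd: float
    median: float
    mad: float


def control_stats(values, trim: float = 0.05, mad_scale: bool = True) -> ControlStats:
    """Location/dispersion summaries with right-truncation of the top ``trim``.

    Truncation removes the ``ceil(trim * n)`` largest observations, the
    deterministic reading of "excluding the uppermost 5%"; the sample SD
    uses the n-1 denominator; the MAD is ``median(|x - median|)`` times
    1.4826 when ``mad_scale`` is on.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 control observations")
    if not 0 <= trim < 1:
        raise ValueError("trim must be in [0, 1)")
    n = int(x.size)
    n_cut = math.ceil(trim * n)
    trimmed = np.sort(x)[: n - n_cut] if n_cut else np.sort(x)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad_scale:
        mad *= MAD_CONSISTENCY
    return ControlStats(
        n_obs=n,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        trimmed_n=int(trimmed.size),
        trimmed_mean=float(np.mean(trimmed)),
        trimmed_sd=float(np.std(trimmed, ddof=1)) if trimmed.size > 1 else 0.0,
        median=med,
        mad=mad,
    )


def bmr_study_specific(
    db: StudyDatabase, technology: str, aggregate: str = "median"
) -> BMRResult:
    """BMR from study-specific control SDs: aggregate of per-study SD/mean."""
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    per_study = extract_controls(db, technology, per_study=True)
    ratios = [
        float(np.std(v, ddof=1) / np.mean(v))
        for v in per_study.values()
        if np.size(v) >= 2
    ]
    if not ratios:
        raise ValueError(
            f"no {technology} study has >= 2 control animals; "
            "study-specific SDs are undefined"
        )
    agg = np.median if aggregate == "median" else np.mean
    return BMRResult(method="sd_study", bmr=float(agg(ratios)), n_basis=len(ratios))


def bmr_historical_sd(controls, trim: float = 0.05) -> BMRResult:
    """BMR from the right-truncated pooled historical-control distribution."""
    stats = control_stats(controls, trim=trim)
    return BMRResult(
        method="sd_hist_trunc",
        bmr=stats.trimmed_sd / stats.trimmed_mean,
        n_basis=stats.n_obs,
    )


def bmr_historical_mad(controls, mad_scale: bool = True) -> BMRResult:
    """BMR from the MAD of pooled historical controls (robust to outliers)."""
    stats = control_stats(controls, trim=0.0, mad_scale=mad_scale)
    if stats.median <= 0:
        raise ValueError("control median must be positive")
    return BMRResult(
        method="mad_hist", bmr=stats.mad / stats.median, n_basis=stats.n_obs
    )
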