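"""Effect-size-theory benchmark responses from within-group variance.

Slob's effect-size theory links the within-group standard deviation of
log-responses, ``s = sqrt(var)``, to the maximum fold change ``c`` of an
endpoint through the empirical proportionality ``ln(c) ~= k * s`` with
``k = 7`` (90% CI 5.9-8.9, estimated across 27 toxicological endpoints).
Taking the critical effect size as 1/8 of the log-transformed maximum
effect gives the benchmark response

    BMR = exp(fraction * k * s) - 1        (fraction = 1/8 by default)

or, when ``c`` itself is well estimated, the equivalent ``c``-based route

    BMR = c**fraction - 1.

Both routes agree exactly whenever ``ln(c) = k * s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Slob proportionality constant between ln(c) and s, with its 90% CI.
DEFAULT_K = 7.0
K_CI90 = (5.9, 8.9)
#: Critical effect size as a fraction of the log-transformed maximum effect.
DEFAULT_FRACTION = 0.125


@dataclass
class BMRResult:
    """A benchmark response (fractional increase over the control mean)."""

    method: str  # one of: es_var, es_c, sd_study, sd_hist_trunc, mad_hist
    bmr: float
    interval: tuple[float, float] | None = None
    n_basis: int | None = None

    def __post_init__(self) -> None:
        if self.bmr < 0:
            raise ValueError("bmr must be >= 0")
        if self.interval is not None:
            lo, hi = self.interval
            if not lo <= self.bmr <= hi:
                raise ValueError("interval must contain the bmr point estimate")

    @property
    def percent(self) -> float:
        """BMR as a percent change from control, rounded to one decimal."""
        return round(100.0 * self.bmr, 1)


def bmr_from_var(
    var: float,
    k: float = DEFAULT_K,
    fraction: float = DEFAULT_FRACTION,
    n_basis: int | None = None,
) -> BMRResult:
    """BMR from the within-group variance of log-responses."""
    if var < 0:
        raise ValueError("var must be >= 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    bmr = math.exp(fraction * k * math.sqrt(var)) - 1.0
    return BMRResult(method="es_var", bmr=bmr, n_basis=n_basis)


def bmr_interval_from_var_ci(
    ci90_var: tuple[float, float],
    k: float = DEFAULT_K,
    fraction: float = DEFAULT_FRACTION,
) -> tuple[float, float]:
    """Propagate a var confidence interval through the (monotone) BMR map."""
    lo, hi = ci90_var
    if not 0 <= lo <= hi:
        raise ValueError("interval must satisfy 0 <= low <= high")
    return (
        bmr_from_var(lo, k, fraction).bmr,
        bmr_from_var(hi, k, fraction).bmr if math.isfinite(hi) else math.inf,
    )


def bmr_from_c(
    c: float,
    fraction: float = DEFAULT_FRACTION,
    n_basis: int | None = None,
) -> BMRResult:
    """BMR from the maximum fold change ``c`` (critical effect size route)."""
    if c <= 1:
        raise ValueError("c must be > 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return BMRResult(method="es_c", bmr=c**fraction - 1.0, n_basis=n_basis)


def bmr_k_sensitivity(
    var: float,
    k_ci: tuple[float, float] = K_CI90,
    fraction: float = DEFAULT_FRACTION,
) -> tuple[float, float]:
    """BMR recomputed at the bounds of the proportionality constant's 90% CI."""
    return (
        bmr_from_var(var, k_ci[0], fraction).bmr,
        bmr_from_var(var, k_ci[1], fraction).bmr,
    )
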