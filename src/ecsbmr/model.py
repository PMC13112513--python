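"""Four-parameter exponential dose-response model with lognormal error.

The mean curve is the classic four-parameter exponential used for
continuous toxicological endpoints::

    mean(x) = a * [c - (c - 1) * exp(-(x / b)^d)]

with ``a`` the mean background response at dose 0, ``b`` the potency
parameter (dose units), ``c`` the maximum fold increase over background
(``mean -> a*c`` as dose grows) and ``d`` the log-steepness.  Observations
are modelled as lognormal around the mean curve:
``ln(y) ~ Normal(ln(mean(x)), var)`` with a single within-group variance
``var`` shared across dose groups (and, in combined fits, across datasets).

Combined fits estimate one ``(c, d, var)`` triple across many datasets
while every dataset keeps its own ``(a_i, b_i)``.  The likelihood is
separable: for fixed ``(c, d)``, ``ln a_i`` has a closed-form optimum and
``b_i`` is a one-dimensional search per dataset, which keeps 47-dataset
fits fast.  ``var`` is concentrated out analytically; the reported ``var``
is the degrees-of-freedom corrected residual variance (see ``FitResult``).

Confidence intervals are profile-likelihood intervals at the chi-square
(1 df) threshold; the upper bound for ``c`` is reported as ``+inf`` when
the profile never crosses the threshold below a parameter cap, which is
the expected behaviour for data without a high-dose plateau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .dataio import Dataset
from .errors import FitError

__all__ = [
    "ModelParams",
    "FitOptions",
    "FitResult",
    "BMDResult",
    "model_mean",
    "log_likelihood",
    "fit_single",
    "fit_combined",
    "profile_ci",
    "bmd_at_bmr",
]

_CHI2_1 = stats.chi2(df=1)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the exponential mean curve for one dataset."""

    a: float  # background mean response, mutations per 1e8 bp
    b: float  # potency, dose units (mg/kg BW/day)
    c: float  # maximum fold increase over background
    d: float  # log-steepness

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.d > 0):
            raise ValueError("a, b and d must be positive")
        if not self.c > 1:
            raise ValueError("c must exceed 1 for an increasing response")


def model_mean(params: ModelParams, dose):
    """Mean response at ``dose`` (scalar or array); ``mean(0) = a``."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(over="ignore"):
        t = np.exp(-np.power(dose / params.b, params.d))
    out = params.a * (params.c - (params.c - 1.0) * t)
    return float(out) if out.ndim == 0 else out


def log_likelihood(params, data, var: float) -> float:
    """Lognormal log-likelihood of a dataset (or list of datasets).

    The convention is the density of the *log-response*:
    ``sum_i logN(ln y_i; ln mean(x_i), var)``.  The same convention is used
    throughout fitting and profiling.  ``params`` is a single
    :class:`ModelParams` for one dataset, or a ``{dataset_id: ModelParams}``
    map for a list of datasets.
    """
    if var <= 0:
        raise ValueError("var must be > 0")
    if isinstance(data, Dataset):
        pairs = [(params, data)]
    else:
        pairs = [(params[ds.dataset_id], ds) for ds in data]
    total = 0.0
    for p, ds in pairs:
        dose, resp = ds.observations()
        if np.any(resp <= 0):
            raise ValueError(
                "responses must be positive under the lognormal model; "
                "see the zero-response policy in the data layer"
            )
        resid = np.log(resp) - np.log(model_mean(p, dose))
        total += float(
            -0.5 * resp.size * math.log(2 * math.pi * var)
            - np.sum(resid**2) / (2 * var)
        )
    return total


@dataclass
class FitOptions:
    """Optimizer configuration for single and combined fits.

    ``n_starts`` seeded multi-starts guard against local optima in the
    shared ``(c, d)`` search; ``d_bounds`` are steepness guardrails;
    ``c_cap`` is the cap above which the ``c`` profile is declared
    unbounded; ``profile_c`` toggles the (comparatively expensive) ``c``
    interval.
    """

    n_starts: int = 10
    seed: int = 1
    d_bounds: tuple[float, float] = (0.25, 8.0)
    share_d: bool = True
    fix_d: float | None = None
    c_cap: float = 1e6
    profile_c: bool = True
    level: float = 0.90
    b_span: float = 50.0
    n_b_grid: int = 41
    maxiter: int = 400


@dataclass
class FitResult:
    """Result of a maximum-likelihood fit.

    ``var`` is the reported within-group variance of log-responses: the
    degrees-of-freedom corrected residual variance ``SSE / (N - p)`` with
    ``p`` the number of mean-curve parameters.  The raw concentrated MLE
    ``SSE / N`` is kept as ``var_mle`` (it satisfies the mean-squared
    log-residual identity at the optimum); with many dataset-specific
    ``(a_i, b_i)`` pairs the raw MLE is biased low by roughly ``p/N``,
    which matters at this package's typical ``p ~ 100, N ~ 1000``.
    """

    per_dataset: dict[str, tuple[float, float]]
    shared: tuple[float, float | None]
    var: float
    var_mle: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    d_fixed: bool = False
    per_dataset_d: dict[str, float] | None = None
    ci90_var: tuple[float, float] | None = None
    ci90_c: tuple[float, float] | None = None
    level: float = 0.90
    seed: int = 1

    @property
    def c(self) -> float:
        return self.shared[0]

    @property
    def d(self) -> float | None:
        return self.shared[1]

    @property
    def sse(self) -> float:
        return self.var_mle * self.n_obs

    def params_for(self, dataset_id: str) -> ModelParams:
        a, b = self.per_dataset[dataset_id]
        d = self.shared[1]
        if d is None:
            d = self.per_dataset_d[dataset_id]
        return ModelParams(a=a, b=b, c=self.shared[0], d=d)


@dataclass
class BMDResult:
    """A benchmark dose at a given benchmark response (fraction over background)."""

    bmd: float
    bmr: float
    bmdl: float | None = None
    bmdu: float | None = None
    level: float = 0.90


# ---------------------------------------------------------------------------
# internal machinery


class _Stacked:
    """Observations of one or more datasets stacked into flat arrays."""

    def __init__(self, datasets: list[Dataset]):
        self.ids = [ds.dataset_id for ds in datasets]
        dose_parts, logy_parts = [], []
        for ds in datasets:
            dose, resp = ds.observations()
            dose_parts.append(dose)
            logy_parts.append(np.log(resp))
        self.dose = np.concatenate(dose_parts)
        self.logy = np.concatenate(logy_parts)
        self.n_k = np.array([p.size for p in dose_parts])
        self.starts = np.concatenate([[0], np.cumsum(self.n_k)[:-1]]).astype(int)
        self.n_obs = int(self.dose.size)
        self.ds_index = np.repeat(np.arange(len(datasets)), self.n_k)
        # per-dataset dose scale anchors the b search
        self.scale = np.array([ds.doses.max() for ds in datasets])
        self.scale = np.where(self.scale > 0, self.scale, 1.0)

    def grid_cache(self, b_span: float, n_b_grid: int):
        """Precompute log(dose / (scale * grid_multiplier)) for the b grid."""
        self.mult = np.exp(np.linspace(-math.log(b_span), math.log(b_span), n_b_grid))
        ratio = self.dose / self.scale[self.ds_index]
        with np.errstate(divide="ignore"):
            ln_ratio = np.where(ratio > 0, np.log(np.maximum(ratio, 1e-300)), -np.inf)
        # lnX[i, j] = ln(dose_i / (scale_i * mult_j))
        self.lnX = ln_ratio[:, None] - np.log(self.mult)[None, :]

    # -- SSE with a_i concentrated -----------------------------------------

    def _sse_from_lng(self, lng):
        """Per-dataset SSE given ln g per observation (2-D: obs x grid)."""
        z = self.logy[:, None] - lng
        s1 = np.add.reduceat(z, self.starts, axis=0)
        s2 = np.add.reduceat(z * z, self.starts, axis=0)
        return s2 - s1 * s1 / self.n_k[:, None]

    def sse_grid(self, c: float, d: float):
        """Min-over-grid SSE per dataset with parabolic refinement.

        Returns (total_sse, lnb_per_dataset) where lnb are refined grid
        optima usable as warm starts.
        """
        with np.errstate(over="ignore", under="ignore"):
            p = np.exp(d * self.lnX)
            e = np.exp(-p)
        lng = np.log(c - (c - 1.0) * e)
        sse = self._sse_from_lng(lng)  # (K, n_grid)
        j = np.argmin(sse, axis=1)
        k = np.arange(sse.shape[0])
        jc = np.clip(j, 1, sse.shape[1] - 2)
        y1, y2, y3 = sse[k, jc - 1], sse[k, jc], sse[k, jc + 1]
        denom = y1 - 2 * y2 + y3
        ok = (denom > 1e-300) & (j == jc)
        frac = np.where(ok, 0.5 * (y1 - y3) / np.maximum(denom, 1e-300), 0.0)
        frac = np.clip(frac, -1.0, 1.0)
        ymin = np.where(ok, y2 - 0.125 * (y1 - y3) ** 2 / np.maximum(denom, 1e-300), y2)
        ymin = np.minimum(ymin, y2)
        step = math.log(self.mult[1] / self.mult[0])
        lnb = np.log(self.scale) + np.log(self.mult[jc]) + frac * step
        return float(np.sum(ymin)), lnb

    def sse_exact(self, c: float, d, lnb: np.ndarray):
        """Exact SSE at given per-dataset ln b (and scalar or per-dataset d)."""
        b_obs = np.exp(lnb)[self.ds_index]
        d_obs = d[self.ds_index] if isinstance(d, np.ndarray) else d
        with np.errstate(over="ignore", under="ignore"):
            p = np.power(self.dose / b_obs, d_obs)
            e = np.exp(-p)
        lng = np.log(c - (c - 1.0) * e)
        z = self.logy - lng
        s1 = np.add.reduceat(z, self.starts)
        s2 = np.add.reduceat(z * z, self.starts)
        sse_k = s2 - s1 * s1 / self.n_k
        lna = s1 / self.n_k
        return float(np.sum(sse_k)), lna


def _u_to_c(u: float) -> float:
    return 1.0 + math.exp(u)


def _heuristic_start(datasets: list[Dataset]) -> tuple[float, float]:
    folds = []
    for ds in datasets:
        gm = {g.dose: float(np.exp(np.mean(np.log(g.responses)))) for g in ds.groups}
        a0 = gm[0.0]
        folds.append(max(gm.values()) / a0)
    c0 = float(np.clip(max(folds), 1.5, 500.0))
    return c0, 1.0


def _fit_core(datasets: list[Dataset], opts: FitOptions):
    """Maximize the combined lognormal likelihood; returns the fitted state."""
    st = _Stacked(datasets)
    st.grid_cache(opts.b_span, opts.n_b_grid)
    K = len(datasets)
    lo_v, hi_v = math.log(opts.d_bounds[0]), math.log(opts.d_bounds[1])
    u_lo, u_hi = math.log(1e-6), math.log(opts.c_cap - 1.0)
    rng = np.random.default_rng(opts.seed)

    d_is_fixed = opts.fix_d is not None
    if d_is_fixed:
        d_fix = float(opts.fix_d)

    if opts.share_d or d_is_fixed:
        if d_is_fixed:
            def outer(x):
                return st.sse_grid(_u_to_c(x[0]), d_fix)[0]
            bounds = [(u_lo, u_hi)]
        else:
            def outer(x):
                return st.sse_grid(_u_to_c(x[0]), math.exp(x[1]))[0]
            bounds = [(u_lo, u_hi), (lo_v, hi_v)]

        c0, d0 = _heuristic_start(datasets)
        starts = [np.array([math.log(c0 - 1.0), 0.0][: len(bounds)])]
        for _ in range(max(opts.n_starts - 1, 0)):
            u = np.clip(math.log(c0 - 1.0) + rng.normal(0, 1.5), u_lo, u_hi)
            s = [u] if d_is_fixed else [u, rng.uniform(lo_v, hi_v)]
            starts.append(np.array(s))

        best = None
        for x0 in starts:
            res = optimize.minimize(
                outer,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": opts.maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        u_hat = best.x[0]
        d_hat = d_fix if d_is_fixed else math.exp(best.x[1])
        _, lnb0 = st.sse_grid(_u_to_c(u_hat), d_hat)

        # joint polish over (u [, v], lnb_1..K)
        lnb_bounds = [(ls - 6.0, ls + 6.0) for ls in np.log(st.scale)]
        if d_is_fixed:
            theta0 = np.concatenate([[u_hat], lnb0])
            pbounds = [(u_lo, u_hi)] + lnb_bounds

            def joint(theta):
                return st.sse_exact(_u_to_c(theta[0]), d_fix, theta[1:])[0]
        else:
            theta0 = np.concatenate([[u_hat, math.log(d_hat)], lnb0])
            pbounds = [(u_lo, u_hi), (lo_v, hi_v)] + lnb_bounds

            def joint(theta):
                return st.sse_exact(_u_to_c(theta[0]), math.exp(theta[1]), theta[2:])[0]

        pol = optimize.minimize(
            joint, theta0, method="L-BFGS-B", bounds=pbounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        theta = pol.x if pol.fun <= joint(theta0) else theta0
        u_hat = theta[0]
        d_hat = d_fix if d_is_fixed else math.exp(theta[1])
        lnb = theta[1:] if d_is_fixed else theta[2:]
        c_hat = _u_to_c(u_hat)
        sse, lna = st.sse_exact(c_hat, d_hat, lnb)
        n_params = 1 + (0 if d_is_fixed else 1) + 2 * K
        converged = bool(best.success or pol.success)
        d_shared: float | None = d_hat
        d_map = None
    else:
        # per-dataset d: outer 1-D over c, inner grid over (b, d) per dataset
        d_grid = np.exp(np.linspace(lo_v, hi_v, 13))

        def outer1(x):
            c = _u_to_c(x[0])
            per_ds = np.full(K, np.inf)
            for dg in d_grid:
                s, _ = _sse_grid_per_ds(st, c, dg)
                per_ds = np.minimum(per_ds, s)
            return float(np.sum(per_ds))

        def _sse_grid_per_ds(st, c, d):
            with np.errstate(over="ignore", under="ignore"):
                p = np.exp(d * st.lnX)
                e = np.exp(-p)
            lng = np.log(c - (c - 1.0) * e)
            sse = st._sse_from_lng(lng)
            j = np.argmin(sse, axis=1)
            lnb = np.log(st.scale) + np.log(st.mult[j])
            return sse[np.arange(K), j], lnb

        c0, _ = _heuristic_start(datasets)
        res = optimize.minimize(
            outer1, [math.log(c0 - 1.0)], method="Nelder-Mead",
            bounds=[(u_lo, u_hi)],
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": opts.maxiter},
        )
        c_hat = _u_to_c(res.x[0])
        per_ds_best = np.full(K, np.inf)
        lnb0 = np.zeros(K)
        d0 = np.ones(K)
        for dg in d_grid:
            s, lnb_g = _sse_grid_per_ds(st, c_hat, dg)
            upd = s < per_ds_best
            per_ds_best = np.where(upd, s, per_ds_best)
            lnb0 = np.where(upd, lnb_g, lnb0)
            d0 = np.where(upd, dg, d0)
        theta0 = np.concatenate([[res.x[0]], lnb0, np.log(d0)])
        pbounds = (
            [(u_lo, u_hi)]
            + [(ls - 6.0, ls + 6.0) for ls in np.log(st.scale)]
            + [(lo_v, hi_v)] * K
        )

        def joint(theta):
            return st.sse_exact(
                _u_to_c(theta[0]), np.exp(theta[1 + K:]), theta[1:1 + K]
            )[0]

        pol = optimize.minimize(
            joint, theta0, method="L-BFGS-B", bounds=pbounds,
            options={"maxiter": 800, "ftol": 1e-13},
        )
        theta = pol.x if pol.fun <= joint(theta0) else theta0
        c_hat = _u_to_c(theta[0])
        lnb = theta[1:1 + K]
        d_vec = np.exp(theta[1 + K:])
        sse, lna = st.sse_exact(c_hat, d_vec, lnb)
        n_params = 1 + 3 * K
        converged = bool(res.success or pol.success)
        d_shared = None
        d_map = {i: float(dv) for i, dv in zip(st.ids, d_vec)}

    return st, c_hat, d_shared, d_map, lnb, lna, sse, n_params, converged


def _var_profile_ci(var_hat: float, nu: int, level: float) -> tuple[float, float]:
    """Closed-form profile interval for var: the profiled mean parameters do
    not depend on var, so the deviance is nu*[ln(v/vhat) + vhat/v - 1]."""
    if var_hat <= 0 or nu <= 0:
        return (var_hat, var_hat)
    q = float(_CHI2_1.ppf(level)) if level > 0 else 0.0
    if q == 0.0:
        return (var_hat, var_hat)

    def dev(v):
        return nu * (math.log(v / var_hat) + var_hat / v - 1.0) - q

    lo = optimize.brentq(dev, var_hat * 1e-8, var_hat)
    hi = optimize.brentq(dev, var_hat, var_hat * 1e8)
    return (float(lo), float(hi))


def _profile_c_interval(st, fit, opts: FitOptions, level: float):
    """Profile-likelihood interval for the shared maximum fold change c."""
    q = float(_CHI2_1.ppf(level)) if level > 0 else 0.0
    if q == 0.0:
        return (fit["c"], fit["c"])
    nu = st.n_obs - fit["n_params"]
    sse_min = fit["sse"]
    lo_v, hi_v = math.log(opts.d_bounds[0]), math.log(opts.d_bounds[1])
    d_is_fixed = fit["d_fix"] is not None
    # wide b box: large c trades off against large b along a near-flat ridge
    # (the power-law limit), which must stay reachable while profiling c
    lnb_bounds = [(ls - 6.0, ls + 40.0) for ls in np.log(st.scale)]
    state = {"x": None}

    def dev(u):
        c = _u_to_c(u)
        if d_is_fixed:
            x0 = state["x"] if state["x"] is not None else fit["lnb"].copy()

            def obj(x):
                return st.sse_exact(c, fit["d_fix"], x)[0]
            bounds = lnb_bounds
        else:
            if state["x"] is not None:
                x0 = state["x"]
            else:
                x0 = np.concatenate([[math.log(fit["d"])], fit["lnb"]])

            def obj(x):
                return st.sse_exact(c, math.exp(x[0]), x[1:])[0]
            bounds = [(lo_v, hi_v)] + lnb_bounds
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        state["x"] = res.x
        sse_u = min(res.fun, obj(x0))
        if sse_min <= 0:
            return np.inf if sse_u > 0 else 0.0
        return nu * math.log(sse_u / sse_min) - q

    u_hat = math.log(fit["c"] - 1.0)
    step = 0.5

    # lower bound: walk down until the deviance crosses q
    state["x"] = None
    u_prev, d_prev = u_hat, -q
    lower = 1.0
    u = u_hat - step
    while u > math.log(1e-9):
        val = dev(u)
        if val > 0:
            lower = 1.0 + math.exp(optimize.brentq(dev, u, u_prev, xtol=1e-4))
            break
        u_prev, d_prev = u, val
        u -= step
    # upper bound: walk up; +inf when no crossing below the cap
    state["x"] = None
    u_prev = u_hat
    upper = math.inf
    u = u_hat + step
    u_cap = math.log(opts.c_cap - 1.0)
    while u <= u_cap:
        val = dev(u)
        if val > 0:
            upper = 1.0 + math.exp(optimize.brentq(dev, u_prev, u, xtol=1e-4))
            break
        u_prev = u
        u = min(u + step, u_cap) if u < u_cap else u_cap + 1.0
        step = min(step * 1.6, 2.0)
    return (float(lower), float(upper))


def fit_combined(datasets: list[Dataset], opts: FitOptions | None = None) -> FitResult:
    """Combined ML fit: shared ``(c, d, var)``, dataset-specific ``(a_i, b_i)``.

    Reduces exactly to :func:`fit_single` when one dataset is supplied.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    opts = opts or FitOptions()

    st, c_hat, d_shared, d_map, lnb, lna, sse, n_params, converged = _fit_core(
        datasets, opts
    )
    N = st.n_obs
    var_mle = sse / N
    nu = N - n_params
    if nu <= 0:
        warnings.warn("more mean parameters than observations; var is unreliable")
        nu = max(nu, 1)
    var = sse / nu
    loglik = (
        -0.5 * N * (math.log(2 * math.pi * var_mle) + 1.0)
        if var_mle > 0
        else math.inf
    )
    per_dataset = {
        i: (float(np.exp(la)), float(np.exp(lb)))
        for i, la, lb in zip(st.ids, lna, lnb)
    }
    result = FitResult(
        per_dataset=per_dataset,
        shared=(float(c_hat), None if d_shared is None else float(d_shared)),
        per_dataset_d=d_map,
        var=float(var),
        var_mle=float(var_mle),
        loglik=float(loglik),
        n_obs=N,
        n_params=n_params,
        converged=converged,
        d_fixed=opts.fix_d is not None,
        level=opts.level,
        seed=opts.seed,
    )
    result.ci90_var = _var_profile_ci(result.var, nu, opts.level)
    if opts.profile_c and d_map is None:
        fit_state = {
            "c": result.c,
            "d": d_shared,
            "d_fix": opts.fix_d,
            "lnb": lnb,
            "sse": sse,
            "n_params": n_params,
        }
        result.ci90_c = _profile_c_interval(st, fit_state, opts, opts.level)
    return result


def fit_single(dataset: Dataset, opts: FitOptions | None = None) -> FitResult:
    """ML fit of one dataset; ``d`` is fixed to 1 when fewer than 3 dose levels
    make the steepness unidentifiable (the result is flagged via ``d_fixed``)."""
    opts = opts or FitOptions()
    n_levels = len(set(dataset.doses))
    if n_levels < 3 and opts.fix_d is None:
        warnings.warn(
            f"dataset {dataset.dataset_id!r} has {n_levels} dose levels; "
            "d is unidentifiable and fixed to 1"
        )
        opts = replace(opts, fix_d=1.0)
    elif n_levels == 3:
        warnings.warn(
            f"dataset {dataset.dataset_id!r} has only 3 dose levels; "
            "4-parameter fits may be weakly identified"
        )
    return fit_combined([dataset], opts)


def profile_ci(
    fit: FitResult,
    data,
    param: str,
    level: float = 0.90,
    opts: FitOptions | None = None,
) -> tuple[float, float]:
    """Profile-likelihood interval for ``var`` or ``c`` at the given level."""
    if not fit.converged:
        raise FitError("profile_ci requires a converged fit")
    if param not in ("var", "c"):
        raise ValueError("param must be 'var' or 'c'")
    datasets = [data] if isinstance(data, Dataset) else list(data)
    nu = fit.n_obs - fit.n_params
    if param == "var":
        return _var_profile_ci(fit.var, nu, level)
    if fit.per_dataset_d is not None:
        raise FitError("c profile with per-dataset d is not supported")
    opts = opts or FitOptions(fix_d=1.0 if fit.d_fixed else None)
    st = _Stacked(datasets)
    lnb = np.array([math.log(fit.per_dataset[i][1]) for i in st.ids])
    fit_state = {
        "c": fit.c,
        "d": fit.d,
        "d_fix": fit.d if fit.d_fixed else None,
        "lnb": lnb,
        "sse": fit.sse,
        "n_params": fit.n_params,
    }
    return _profile_c_interval(st, fit_state, opts, level)


# ---------------------------------------------------------------------------
# benchmark dose


def _bmd_closed_form(b: float, c: float, d: float, bmr: float) -> float:
    if not 0 < bmr:
        raise ValueError("bmr must be > 0")
    if bmr >= c - 1.0:
        raise ValueError("BMR exceeds attainable maximum effect (bmr >= c - 1)")
    return b * (-math.log((c - 1.0 - bmr) / (c - 1.0))) ** (1.0 / d)


def bmd_at_bmr(
    obj,
    bmr: float,
    data: Dataset | None = None,
    dataset_id: str | None = None,
    level: float = 0.90,
    opts: FitOptions | None = None,
) -> BMDResult:
    """Benchmark dose at benchmark response ``bmr`` (fractional increase).

    The BMD solves ``mean(bmd) = a*(1 + bmr)`` and has the closed form
    ``bmd = b * [-ln((c-1-bmr)/(c-1))]^(1/d)`` — independent of ``a``.
    When a single dataset is supplied, BMDL/BMDU are computed by profiling
    the likelihood re-parameterized in the BMD.
    """
    if isinstance(obj, FitResult):
        if dataset_id is None:
            if len(obj.per_dataset) != 1:
                raise ValueError("dataset_id required for multi-dataset fits")
            dataset_id = next(iter(obj.per_dataset))
        params = obj.params_for(dataset_id)
    else:
        params = obj
    bmd = _bmd_closed_form(params.b, params.c, params.d, bmr)
    result = BMDResult(bmd=bmd, bmr=bmr, level=level)
    if data is None:
        return result

    # profile in BMD: for fixed bmd, b = bmd / h(c, d, bmr)
    opts = opts or FitOptions()
    st = _Stacked([data])
    base = fit_single(data, replace(opts, profile_c=False))
    sse_min = base.sse
    nu = max(st.n_obs - base.n_params, 1)
    q = float(_CHI2_1.ppf(level)) if level > 0 else 0.0
    bmd_hat = _bmd_closed_form(
        base.per_dataset[data.dataset_id][1], base.c, base.d or 1.0, bmr
    )
    lo_v, hi_v = math.log(opts.d_bounds[0]), math.log(opts.d_bounds[1])
    u_floor = math.log(max(bmr, 1e-9)) + 1e-9  # ensure c - 1 > bmr

    def sse_at_bmd(ln_bmd):
        def obj_fn(x):
            c = 1.0 + math.exp(x[0])
            d = base.d if base.d_fixed else math.exp(x[1])
            h = (-math.log((c - 1.0 - bmr) / (c - 1.0))) ** (1.0 / d)
            lnb = np.array([ln_bmd - math.log(h)])
            return st.sse_exact(c, d, lnb)[0]

        x0 = [math.log(max(base.c - 1.0, bmr * 1.5))]
        bounds = [(u_floor, math.log(opts.c_cap))]
        if not base.d_fixed:
            x0.append(math.log(base.d))
            bounds.append((lo_v, hi_v))
        res = optimize.minimize(
            obj_fn, x0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-5, "fatol": 1e-11, "maxiter": 300},
        )
        return res.fun

    def dev(ln_bmd):
        s = sse_at_bmd(ln_bmd)
        if sse_min <= 0:
            return np.inf if s > 0 else -q
        return nu * math.log(max(s, sse_min) / sse_min) - q

    ln_hat = math.log(bmd_hat)
    bmdl, bmdu = 0.0, math.inf
    prev = ln_hat
    for i in range(1, 30):
        u = ln_hat - 0.35 * i
        if dev(u) > 0:
            bmdl = math.exp(optimize.brentq(dev, u, prev, xtol=1e-5))
            break
        prev = u
    prev = ln_hat
    for i in range(1, 30):
        u = ln_hat + 0.35 * i
        if dev(u) > 0:
            bmdu = math.exp(optimize.brentq(dev, prev, u, xtol=1e-5))
            break
        prev = u
    return BMDResult(bmd=bmd_hat, bmr=bmr, bmdl=float(bmdl), bmdu=float(bmdu), level=level)
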