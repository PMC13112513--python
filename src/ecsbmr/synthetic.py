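"""Synthetic dose-response databases with the structure the analysis assumes.

The generator draws per-animal mutation frequencies as lognormal noise
around four-parameter exponential mean curves: every dataset gets its own
background ``a`` and potency ``b``, while the maximum fold change ``c``,
the log-steepness ``d`` and the within-group log-scale variance ``var``
are shared across datasets — exactly the combined-fit model.  Defaults
emulate the flagship Duplex Sequencing collection: 47 datasets, shared
``var = 0.078`` and ``c = 17.2``, 3-5 treated dose levels plus a matched
dose-0 control per dataset with 3-6 animals per group, and a covariate
design (species, strain, route, times, tissue, fragmentation) matching
the published dataset counts.

A single master seed spawns per-dataset substreams, so enlarging a
database leaves earlier datasets byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import Dataset, DoseGroup, StudyDatabase
from .model import FitOptions, ModelParams, fit_combined, model_mean

#: Covariate design of the emulated DupSeq collection (counts of datasets).
DUPSEQ_COVARIATE_DESIGN: dict[str, dict[str, int]] = {
    "strain": {
        "MutaMouse": 25,
        "BigBlue mouse": 7,
        "BigBlue rat": 4,
        "Sprague Dawley rat": 4,
        "Tg-rasH2 mouse": 3,
        "NMRI mouse": 2,
        "gpt delta mouse": 2,
    },
    "route": {"gavage": 42, "ip": 5},
    "application_time_days": {"28": 26, "3": 6, "1": 4, "90": 4, "180": 4, "70": 2, "72": 1},
    "tissue": {
        "liver": 16,
        "bone marrow": 11,
        "seminiferous tubules": 8,
        "lung": 6,
        "blood": 2,
        "kidney": 2,
        "stomach": 1,
        "spleen": 1,
    },
    "sampling_time_days": {"28": 16, "3": 15, "1": 8, "24": 3, "2": 2, "70": 2, "42": 1},
    "fragmentation_method": {"enzymatic": 32, "sonication": 15},
}

_RAT_STRAINS = {"BigBlue rat", "Sprague Dawley rat"}


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic study database.

    ``a_range`` (mutations per 1e8 bp) and ``b_range`` (as a fraction of
    the top dose) are per-dataset log-uniform draw intervals; ``shared_c``,
    ``shared_d`` and ``var_true`` are the shared truth of the collection.
    ``control_n_total`` forces the pooled number of control animals (e.g.
    216 for the emulated DupSeq historical-control pool).
    """

    n_datasets: int = 47
    technology: str = "DupSeq"
    n_dose_levels: tuple[int, int] = (3, 5)  # treated levels, excluding control
    dose_spacing: float = 2.5  # geometric spacing factor
    top_dose_range: tuple[float, float] = (10.0, 200.0)  # mg/kg BW/day
    n_per_group: tuple[int, int] = (3, 6)
    a_range: tuple[float, float] = (0.5, 5.0)
    b_rel_range: tuple[float, float] = (0.2, 1.5)  # b as fraction of top dose
    shared_c: float = 17.2
    shared_d: float = 1.0
    var_true: float = 0.078
    covariate_design: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DUPSEQ_COVARIATE_DESIGN.items()}
    )
    control_n_total: int | None = None
    seed: int = 1

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.var_true < 0:
            raise ValueError("var_true must be >= 0")
        if self.shared_c <= 1 or self.shared_d <= 0:
            raise ValueError("shared_c must be > 1 and shared_d > 0")
        for lo, hi in (self.a_range, self.b_rel_range, self.top_dose_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive intervals")
        for factor, freq in self.covariate_design.items():
            if sum(freq.values()) != self.n_datasets:
                raise ValueError(
                    f"covariate design for {factor!r} sums to {sum(freq.values())}, "
                    f"expected n_datasets={self.n_datasets}"
                )


def _assign_levels(freq: dict[str, int], n: int, rng: np.random.Generator) -> list[str]:
    levels = [lvl for lvl, cnt in freq.items() for _ in range(cnt)]
    rng.shuffle(levels)
    return levels[:n]


def generate_database(config: SyntheticConfig) -> StudyDatabase:
    """Draw a :class:`StudyDatabase` from the configured generative model."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    design_rng = np.random.default_rng(master.spawn(1)[0])
    ds_seeds = master.spawn(config.n_datasets + 1)[1:]

    assignments: dict[str, list[str]] = {
        factor: _assign_levels(freq, config.n_datasets, design_rng)
        for factor, freq in config.covariate_design.items()
    }
    # species is implied by strain when a strain design is present
    if "strain" in assignments and "species" not in assignments:
        assignments["species"] = [
            "rat" if s in _RAT_STRAINS else "mouse" for s in assignments["strain"]
        ]

    if config.control_n_total is not None:
        base, extra = divmod(config.control_n_total, config.n_datasets)
        control_ns = [base + (1 if i < extra else 0) for i in range(config.n_datasets)]
        if min(control_ns) < 1:
            raise ValueError("control_n_total too small for n_datasets")
    else:
        control_ns = [None] * config.n_datasets

    datasets = []
    for i in range(config.n_datasets):
        rng = np.random.default_rng(ds_seeds[i])
        k_treated = rng.integers(config.n_dose_levels[0], config.n_dose_levels[1] + 1)
        top = math.exp(rng.uniform(*np.log(config.top_dose_range)))
        doses = [0.0] + [
            top / config.dose_spacing**j for j in range(int(k_treated))
        ][::-1]
        a = math.exp(rng.uniform(*np.log(config.a_range)))
        b = top * math.exp(rng.uniform(*np.log(config.b_rel_range)))
        params = ModelParams(a=a, b=b, c=config.shared_c, d=config.shared_d)
        s = math.sqrt(config.var_true)
        groups = []
        for dose in doses:
            if dose == 0.0 and control_ns[i] is not None:
                n = control_ns[i]
            else:
                n = int(rng.integers(config.n_per_group[0], config.n_per_group[1] + 1))
            mu = math.log(model_mean(params, dose))
            responses = np.exp(mu + s * rng.standard_normal(n)) if s > 0 else np.exp(
                np.full(n, mu)
            )
            groups.append(DoseGroup(dose=dose, responses=responses))
        covariates = {f: assignments[f][i] for f in assignments}
        datasets.append(
            Dataset(
                dataset_id=f"{config.technology}-{i + 1:03d}",
                technology=config.technology,
                chemical=f"chem-{i + 1:03d}",
                covariates=covariates,
                groups=groups,
            )
        )
    return StudyDatabase(
        datasets=datasets,
        provenance=f"synthetic (seed={config.seed}, var_true={config.var_true})",
    )


@dataclass
class RecoveryReport:
    """Summary of a parameter-recovery simulation."""

    var_true: float
    c_true: float
    var_hat: list[float]
    ci_var: list[tuple[float, float]]
    c_hat: list[float]
    d_hat: list[float]
    n_nonconverged: int

    @property
    def coverage_var(self) -> float:
        """Fraction of replicates whose 90% var interval covers the truth."""
        return float(
            np.mean([lo <= self.var_true <= hi for lo, hi in self.ci_var])
        )

    @property
    def median_rel_bias_var(self) -> float:
        return float(
            np.median([(v - self.var_true) / self.var_true for v in self.var_hat])
        )

    @property
    def median_rel_ci_width_var(self) -> float:
        return float(
            np.median([(hi - lo) / v for (lo, hi), v in zip(self.ci_var, self.var_hat)])
        )


def recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    fit_opts: FitOptions | None = None,
) -> RecoveryReport:
    """Generate-and-refit simulation: bias, CI coverage and width for var/c.

    Each replicate regenerates the whole database under a replicate-specific
    substream of ``config.seed`` and runs the combined fit.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    fit_opts = fit_opts or FitOptions(n_starts=3, profile_c=False)
    rep_seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    var_hat, ci_var, c_hat, d_hat = [], [], [], []
    n_bad = 0
    for r in range(n_replicates):
        rep_config = SyntheticConfig(**{**config.__dict__, "seed": None})
        rep_config.seed = int(rep_seeds[r].generate_state(1)[0] % (2**31 - 1))
        db = generate_database(rep_config)
        fit = fit_combined(db.datasets, fit_opts)
        if not fit.converged:
            n_bad += 1
        var_hat.append(fit.var)
        ci_var.append(fit.ci90_var)
        c_hat.append(fit.c)
        d_hat.append(fit.d if fit.d is not None else math.nan)
    return RecoveryReport(
        var_true=config.var_true,
        c_true=config.shared_c,
        var_hat=var_hat,
        ci_var=ci_var,
        c_hat=c_hat,
        d_hat=d_hat,
        n_nonconverged=n_bad,
    )
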