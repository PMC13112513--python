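"""Read, validate and normalize dose-response databases of per-animal mutation frequencies.

The on-disk format is a long CSV: one row per animal per dose group, with
required columns ``dataset_id, technology, chemical, dose_mg_kg_day,
mf_per_1e8bp`` and optional covariate columns (species, strain, route,
application_time_days, tissue, sampling_time_days, fragmentation_method,
sex, age, group_size).  Each dataset is a chemical x tissue dose-response
series that must carry its own matched dose-0 (negative control) group.

Responses are mutation frequencies in mutations per 1e8 base pairs; doses
are daily doses in mg/kg body weight per day.  Cumulative dosing schedules
are converted to daily doses with :func:`normalize_daily_dose`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: Error-corrected sequencing technologies the database may contain.
TECHNOLOGIES = ("DupSeq", "HawkSeq", "PECCSeq", "HiFi")

REQUIRED_COLUMNS = (
    "dataset_id",
    "technology",
    "chemical",
    "dose_mg_kg_day",
    "mf_per_1e8bp",
)

COVARIATE_COLUMNS = (
    "species",
    "strain",
    "route",
    "application_time_days",
    "tissue",
    "sampling_time_days",
    "fragmentation_method",
    "sex",
    "age",
    "group_size",
)

_TECH_ALIASES = {
    "dupseq": "DupSeq",
    "duplex": "DupSeq",
    "duplexsequencing": "DupSeq",
    "hawkseq": "HawkSeq",
    "peccseq": "PECCSeq",
    "hifi": "HiFi",
    "pacbiohifi": "HiFi",
}


def canonical_technology(name: str) -> str:
    """Map spelling variants like ``Hawk-Seq`` onto the canonical technology name."""
    key = "".join(ch for ch in str(name).lower() if ch.isalnum())
    try:
        return _TECH_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown technology {name!r}; expected one of {TECHNOLOGIES}"
        ) from None


@dataclass
class DoseGroup:
    """One dose level and its per-animal mutation-frequency observations."""

    dose: float
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.dose = float(self.dose)
        self.responses = np.asarray(self.responses, dtype=float)
        if not math.isfinite(self.dose) or self.dose < 0:
            raise ValidationError(f"dose must be finite and >= 0, got {self.dose}")
        if self.responses.ndim != 1 or self.responses.size < 1:
            raise ValidationError("a dose group needs at least one response")
        if not np.all(np.isfinite(self.responses)):
            raise ValidationError("responses must be finite")
        if np.any(self.responses <= 0):
            raise ValidationError(
                "responses must be strictly positive (the lognormal error model "
                "takes logs); use zero_policy='half_min' at read time to impute zeros"
            )

    @property
    def n(self) -> int:
        return int(self.responses.size)


@dataclass
class Dataset:
    """A chemical/tissue dose-response series with its matched negative control.

    Invariants: exactly one group at dose 0, and at least two distinct dose
    levels overall.
    """

    dataset_id: str
    technology: str
    chemical: str
    covariates: dict[str, str] = field(default_factory=dict)
    groups: list[DoseGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.technology = canonical_technology(self.technology)
        doses = [g.dose for g in self.groups]
        if len(set(doses)) != len(doses):
            raise ValidationError(
                f"dataset {self.dataset_id!r}: duplicate dose levels; "
                "aggregate replicate rows into one group per dose"
            )
        n_control = sum(1 for d in doses if d == 0.0)
        if n_control != 1:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: needs exactly one matched dose-0 "
                f"control group, found {n_control}"
            )
        if len(set(doses)) < 2:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: needs >= 2 distinct dose levels"
            )
        self.groups = sorted(self.groups, key=lambda g: g.dose)

    @property
    def control(self) -> DoseGroup:
        """The matched dose-0 group."""
        return next(g for g in self.groups if g.dose == 0.0)

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups])

    @property
    def n_obs(self) -> int:
        return sum(g.n for g in self.groups)

    def observations(self) -> tuple[np.ndarray, np.ndarray]:
        """Long-form (dose, response) arrays, one entry per animal."""
        dose = np.concatenate([np.full(g.n, g.dose) for g in self.groups])
        resp = np.concatenate([g.responses for g in self.groups])
        return dose, resp


@dataclass
class StudyDatabase:
    """A curated collection of datasets for one or more ECS technologies."""

    datasets: list[Dataset] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate dataset_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    @property
    def technologies(self) -> list[str]:
        return sorted({d.technology for d in self.datasets})

    def get(self, dataset_id: str) -> Dataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def filter(self, technology: str) -> "StudyDatabase":
        tech = canonical_technology(technology)
        return StudyDatabase(
            datasets=[d for d in self.datasets if d.technology == tech],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per animal (the CSV layout)."""
        rows = []
        for ds in self.datasets:
            for g in ds.groups:
                for y in g.responses:
                    row = {
                        "dataset_id": ds.dataset_id,
                        "technology": ds.technology,
                        "chemical": ds.chemical,
                        "dose_mg_kg_day": g.dose,
                        "mf_per_1e8bp": y,
                    }
                    row.update(ds.covariates)
                    rows.append(row)
        return pd.DataFrame(rows)


def normalize_daily_dose(cumulative_dose: float, treatment_duration_days: float) -> float:
    """Convert a cumulative administered dose to a best-estimate daily dose.

    For intermittent dosing schedules the cumulative dose delivered over the
    study is divided by the treatment duration in days.
    """
    if treatment_duration_days <= 0:
        raise ValueError("treatment_duration_days must be > 0")
    if cumulative_dose < 0:
        raise ValueError("cumulative_dose must be >= 0")
    return cumulative_dose / treatment_duration_days


def read_database(
    path,
    schema_config: dict[str, str] | None = None,
    zero_policy: str = "reject",
) -> StudyDatabase:
    """Read a long-format CSV into a validated :class:`StudyDatabase`.

    Parameters
    ----------
    path
        CSV file with the columns documented in the module docstring.
    schema_config
        Optional map from the canonical column names to the names used in
        the file, absorbing dialect differences
        (e.g. ``{"dose_mg_kg_day": "dose"}``).
    zero_policy
        ``"reject"`` (default) raises on zero responses; ``"half_min"``
        replaces each zero with half the smallest positive response in the
        same dataset.
    """
    if zero_policy not in ("reject", "half_min"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    df = pd.read_csv(path, dtype=str)
    colmap = dict(schema_config or {})
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    for col in ("dose_mg_kg_day", "mf_per_1e8bp"):
        # Python's float() is correctly rounded, so values written with repr
        # round-trip bit-exactly (pandas' fast parser can be 1 ulp off)
        parsed = np.empty(len(df))
        for i, raw in enumerate(df[col].to_numpy()):
            rownum = i + 2  # header line plus 1-based numbering
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                raise ParseError(f"empty value in column {col!r} at file row {rownum}")
            try:
                parsed[i] = float(raw)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {raw!r} in column {col!r} at file row {rownum}"
                ) from None
        df[col] = parsed

    datasets, bad_ids = [], []
    for ds_id, sub in df.groupby("dataset_id", sort=True):
        resp = sub["mf_per_1e8bp"].to_numpy(dtype=float)
        if np.any(resp == 0):
            if zero_policy == "reject":
                raise ValidationError(
                    f"dataset {ds_id!r} contains zero mutation frequencies; the "
                    "lognormal model requires positive responses. Re-read with "
                    "zero_policy='half_min' to impute half the smallest positive "
                    "value, or clean the data."
                )
            positive = resp[resp > 0]
            if positive.size == 0:
                raise ValidationError(f"dataset {ds_id!r}: all responses are zero")
            resp = np.where(resp == 0, positive.min() / 2.0, resp)
        sub = sub.assign(mf_per_1e8bp=resp)
        covariates = {
            c: sub[c].iloc[0]
            for c in COVARIATE_COLUMNS
            if c in sub.columns and pd.notna(sub[c].iloc[0])
        }
        groups = [
            DoseGroup(dose=dose, responses=g["mf_per_1e8bp"].to_numpy(dtype=float))
            for dose, g in sub.groupby("dose_mg_kg_day", sort=True)
        ]
        try:
            datasets.append(
                Dataset(
                    dataset_id=str(ds_id),
                    technology=sub["technology"].iloc[0],
                    chemical=str(sub["chemical"].iloc[0]),
                    covariates=covariates,
                    groups=groups,
                )
            )
        except ValidationError:
            bad_ids.append(str(ds_id))
    if bad_ids:
        raise ValidationError(
            "dataset(s) violate structural invariants (matched dose-0 control "
            f"and >= 2 dose levels): {bad_ids}"
        )
    return StudyDatabase(datasets=datasets, provenance=f"read from {path}")


def write_database(db: StudyDatabase, path) -> None:
    """Write a database to long-format CSV; values round-trip at full precision."""
    df = db.to_frame()
    df.to_csv(path, index=False)


def extract_controls(
    db: StudyDatabase, technology: str, per_study: bool = False
):
    """Collect all per-animal dose-0 (negative control) responses for a technology.

    Returns a pooled 1-D array, or a ``{dataset_id: array}`` map when
    ``per_study`` is set.  An absent technology yields an empty result with a
    warning rather than an error.
    """
    tech = canonical_technology(technology)
    subset = [d for d in db.datasets if d.technology == tech]
    if not subset:
        warnings.warn(f"no datasets with technology {tech!r} in database", stacklevel=2)
        return {} if per_study else np.array([])
    if per_study:
        return {d.dataset_id: d.control.responses.copy() for d in subset}
    return np.concatenate([d.control.responses for d in subset])


def write_json(db: StudyDatabase, path) -> None:
    """Machine-readable JSON export of a database."""
    payload = {
        "provenance": db.provenance,
        "datasets": [
            {
                "dataset_id": d.dataset_id,
                "technology": d.technology,
                "chemical": d.chemical,
                "covariates": d.covariates,
                "groups": [
                    {"dose": g.dose, "responses": g.responses.tolist()}
                    for g in d.groups
                ],
            }
            for d in db.datasets
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_json(path) -> StudyDatabase:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    datasets = [
        Dataset(
            dataset_id=d["dataset_id"],
            technology=d["technology"],
            chemical=d["chemical"],
            covariates=d.get("covariates", {}),
            groups=[DoseGroup(g["dose"], g["responses"]) for g in d["groups"]],
        )
        for d in payload["datasets"]
    ]
    return StudyDatabase(datasets=datasets, provenance=payload.get("provenance", ""))
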