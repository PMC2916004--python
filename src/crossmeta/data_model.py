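"""Study-level data containers, CSV round-trip, and classical log-OR summaries.

A comparative study contributes a 2x2 table (events / totals in a treatment
and a control arm) plus zero or more per-arm covariate values (age in years,
and proportion-type covariates such as fraction male or fraction with cardiac
disease).  Studies are typed *randomised* or *non_randomised*; the hierarchical
models treat the two types as exchangeable groups nested under an overall
population effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "StudyType",
    "ArmData",
    "StudyRecord",
    "Dataset",
    "NormalSummary",
    "ValidationError",
    "DegenerateStudyError",
    "read_dataset",
    "write_dataset",
    "to_normal_summary",
    "arm_difference",
]

#: covariates whose values are proportions and must lie in [0, 1]
PROPORTION_HINTS = ("male", "gender", "cardiac", "pulmonary", "renal")

COUNT_COLUMNS = ["r_T", "n_T", "r_C", "n_C"]


class ValidationError(ValueError):
    """Raised when a study or dataset violates a structural invariant."""


class DegenerateStudyError(ValueError):
    """Raised when a 2x2 table carries no information about the odds ratio."""


class StudyType(str, Enum):
    RANDOMISED = "randomised"
    NON_RANDOMISED = "non_randomised"


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _looks_like_proportion(name: str) -> bool:
    lowered = name.lower()
    return any(h in lowered for h in PROPORTION_HINTS)


@dataclass
class ArmData:
    """One study arm: event count, arm size, and covariate values.

    ``covariates`` maps covariate name to a float or ``None`` (missing).
    """

    events: int
    total: int
    covariates: dict[str, float | None] = field(default_factory=dict)

    def validate(self, study_id: str = "?") -> None:
        if self.total < 1:
            raise ValidationError(f"study {study_id!r}: arm total must be >= 1, got {self.total}")
        if not (0 <= self.events <= self.total):
            raise ValidationError(
                f"study {study_id!r}: events must satisfy 0 <= events <= total, "
                f"got events={self.events}, total={self.total}"
            )
        for name, value in self.covariates.items():
            if _is_missing(value):
                continue
            if _looks_like_proportion(name) and not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"study {study_id!r}: proportion covariate {name!r} outside [0,1]: {value}"
                )


@dataclass
class StudyRecord:
    """A single comparative study with treatment (T) and control (C) arms."""

    study_id: str
    study_type: StudyType
    treatment_arm: ArmData
    control_arm: ArmData

    def validate(self) -> None:
        self.treatment_arm.validate(self.study_id)
        self.control_arm.validate(self.study_id)
        if set(self.treatment_arm.covariates) != set(self.control_arm.covariates):
            raise ValidationError(
                f"study {self.study_id!r}: arms declare different covariate sets"
            )


@dataclass
class Dataset:
    """An ordered collection of studies plus the adjustment covariate names."""

    studies: list[StudyRecord]
    covariate_names: list[str] = field(default_factory=list)

    def validate(self, require_both_types: bool = False) -> None:
        for study in self.studies:
            study.validate()
            for name in self.covariate_names:
                if name not in study.treatment_arm.covariates:
                    raise ValidationError(
                        f"covariate {name!r} absent from study {study.study_id!r}"
                    )
        if require_both_types:
            types = {s.study_type for s in self.studies}
            if len(types) < 2:
                raise ValidationError(
                    "a three-level model needs at least one study of each type"
                )

    def by_type(self, study_type: StudyType) -> list[StudyRecord]:
        return [s for s in self.studies if s.study_type == study_type]

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        idx = list(indices)
        return Dataset([self.studies[i] for i in idx], list(self.covariate_names))


@dataclass(frozen=True)
class NormalSummary:
    """A study's classical log odds ratio and its Woolf variance."""

    log_effect: float
    variance: float

    def __post_init__(self):
        if not self.variance > 0:
            raise ValidationError(f"variance must be positive, got {self.variance}")


# ---------------------------------------------------------------------------
# CSV I/O.  Schema: study_id, study_type, r_T, n_T, r_C, n_C, <cov>_T, <cov>_C
# ---------------------------------------------------------------------------


def _covariate_names_from_header(columns: Sequence[str]) -> list[str]:
    fixed = {"study_id", "study_type", *COUNT_COLUMNS}
    names: list[str] = []
    extras = [c for c in columns if c not in fixed]
    for col in extras:
        if col.endswith("_T"):
            base = col[:-2]
            if f"{base}_C" not in extras:
                raise ValidationError(f"covariate column {col!r} lacks its _C partner")
            names.append(base)
        elif not col.endswith("_C"):
            raise ValidationError(
                f"unrecognised column {col!r}; covariates use the _T/_C suffix pair"
            )
    return names


def read_dataset(path: str | Path, format_config: Mapping | None = None) -> Dataset:
    """Read a dataset from CSV, validating counts and study types.

    ``format_config`` is forwarded to :func:`pandas.read_csv` (delimiter etc.).
    Empty cells become missing covariate values.
    """
    opts = dict(format_config or {})
    frame = pd.read_csv(path, dtype={"study_id": str}, **opts)
    required = ["study_id", "study_type", *COUNT_COLUMNS]
    for col in required:
        if col not in frame.columns:
            raise ValidationError(f"missing required column {col!r}")
    cov_names = _covariate_names_from_header(list(frame.columns))

    accepted = [t.value for t in StudyType]
    studies: list[StudyRecord] = []
    for _, row in frame.iterrows():
        sid = str(row["study_id"])
        label = str(row["study_type"]).strip()
        try:
            stype = StudyType(label)
        except ValueError:
            raise ValidationError(
                f"study {sid!r}: unknown study_type {label!r}; accepted: {accepted}"
            ) from None
        arms = {}
        for arm_key, suffix in (("treatment_arm", "T"), ("control_arm", "C")):
            covs = {
                name: (None if _is_missing(row[f"{name}_{suffix}"]) else float(row[f"{name}_{suffix}"]))
                for name in cov_names
            }
            arms[arm_key] = ArmData(
                events=int(row[f"r_{suffix}"]), total=int(row[f"n_{suffix}"]), covariates=covs
            )
        record = StudyRecord(study_id=sid, study_type=stype, **arms)
        record.validate()
        studies.append(record)
    return Dataset(studies=studies, covariate_names=cov_names)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the CSV schema read by :func:`read_dataset`."""
    rows = []
    for s in dataset.studies:
        row: dict = {
            "study_id": s.study_id,
            "study_type": s.study_type.value,
            "r_T": s.treatment_arm.events,
            "n_T": s.treatment_arm.total,
            "r_C": s.control_arm.events,
            "n_C": s.control_arm.total,
        }
        for name in dataset.covariate_names:
            for suffix, arm in (("T", s.treatment_arm), ("C", s.control_arm)):
                value = arm.covariates.get(name)
                row[f"{name}_{suffix}"] = "" if _is_missing(value) else repr(float(value))
        rows.append(row)
    columns = ["study_id", "study_type", *COUNT_COLUMNS]
    for name in dataset.covariate_names:
        columns += [f"{name}_T", f"{name}_C"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Classical summaries
# ---------------------------------------------------------------------------


def to_normal_summary(study: StudyRecord, correction: float = 0.5) -> NormalSummary:
    """Log odds ratio and Woolf variance for one study's 2x2 table.

    The continuity ``correction`` is added to all four cells, but only when at
    least one cell is zero.  The binomial-likelihood models need no correction;
    this summary feeds the normal-likelihood (two- and three-level) variants.
    """
    if correction < 0:
        raise ValidationError("correction must be non-negative")
    a = float(study.treatment_arm.events)
    b = float(study.treatment_arm.total - study.treatment_arm.events)
    c = float(study.control_arm.events)
    d = float(study.control_arm.total - study.control_arm.events)
    if min(a, b, c, d) == 0.0:
        if correction == 0.0 or (a + c == 0.0) or (b + d == 0.0):
            raise DegenerateStudyError(
                f"study {study.study_id!r}: 2x2 table degenerate for the odds ratio"
            )
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log_effect = math.log((a / b) / (c / d))
    variance = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return NormalSummary(log_effect=log_effect, variance=variance)


def arm_difference(study: StudyRecord, covariate: str) -> float | None:
    """Treatment-minus-control covariate difference; ``None`` if either side missing."""
    if covariate not in study.treatment_arm.covariates:
        raise ValidationError(
            f"covariate {covariate!r} not declared for study {study.study_id!r}"
        )
    t = study.treatment_arm.covariates[covariate]
    c = study.control_arm.covariates[covariate]
    if _is_missing(t) or _is_missing(c):
        return None
    return float(t) - float(c)


def pooled_covariate(study: StudyRecord, covariate: str) -> float | None:
    """Sample-size-weighted whole-study covariate value (the 'aggregate' value)."""
    t = study.treatment_arm.covariates.get(covariate)
    c = study.control_arm.covariates.get(covariate)
    if _is_missing(t) or _is_missing(c):
        return None
    n_t, n_c = study.treatment_arm.total, study.control_arm.total
    return (float(t) * n_t + float(c) * n_c) / (n_t + n_c)
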