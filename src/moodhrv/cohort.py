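"""Cohort construction: inclusion filters, covariate transforms, model table.

The analysis models night-time lnRMSSD as a function of fractional symptom
improvement over an acute bipolar episode. This module turns per-subject
assessment sequences (YMRS totals for mania, HDRS totals for depression)
plus night-level HRV values into the long-format table the regression
models consume:

==============  =======================================================
column          meaning
==============  =======================================================
subject_index   0-based index ``i`` over included subjects
t               assessment index within subject (0 = episode onset)
ln_rmssd        night-level ln RMSSD (ln ms)
I               fractional improvement, ``(score_0 - score_t)/score_0``
M               number of HRV-relevant medication classes at time t
A_std           age, standardized over included subjects (mean 0, sd 1)
S               sex (female = 1, male = 0)
B               baseline severity, onset score / scale maximum
polarity_index  0 = mania, 1 = depression
==============  =======================================================

Inclusion requires at least three assessments with strictly decreasing
scale totals; subjects failing either rule are excluded with a
machine-readable reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, LinkageError, SchemaError, ZeroVarianceError

__all__ = [
    "Polarity",
    "MEDICATION_CLASSES",
    "Assessment",
    "Subject",
    "improvement",
    "baseline_severity",
    "standardize_age",
    "medication_count",
    "apply_inclusion_filters",
    "build_table",
    "read_assessments_csv",
    "write_table_csv",
]

#: Drug classes with a known influence on HRV tracked per assessment.
MEDICATION_CLASSES: tuple[str, ...] = (
    "lithium",
    "ssri",
    "snri",
    "tricyclics",
    "maoi",
    "other_antidepressants",
    "typical_antipsychotic",
    "atypical_antipsychotic",
    "anticonvulsants",
    "beta_blockers",
    "opioids",
    "amphetamines",
    "antihistamines",
    "antiarrhythmic",
    "other_anticholinergic",
    "benzodiazepines",
)


class Polarity(str, enum.Enum):
    """Episode polarity; determines the severity scale and its maximum."""

    MANIA = "mania"
    DEPRESSION = "depression"

    @property
    def scale(self) -> str:
        return "YMRS" if self is Polarity.MANIA else "HDRS"

    @property
    def scale_max(self) -> int:
        # YMRS range [0, 60]; 17-item HDRS range [0, 52]
        return 60 if self is Polarity.MANIA else 52


@dataclass
class Assessment:
    """One clinical assessment with its attached night HRV value."""

    subject_id: str
    t: int
    score: int
    datetime: datetime | None = None
    medication_flags: Mapping[str, bool] = field(default_factory=dict)
    ln_rmssd: float | None = None

    def __post_init__(self) -> None:
        if self.t not in (0, 1, 2, 3):
            raise DomainError(f"assessment index t={self.t} outside {{0,1,2,3}}")
        if self.score < 0:
            raise DomainError(f"scale total {self.score} is negative")
        unknown = set(self.medication_flags) - set(MEDICATION_CLASSES)
        if unknown:
            raise SchemaError(f"unknown medication classes: {sorted(unknown)}")


@dataclass
class Subject:
    subject_id: str
    polarity: Polarity
    age: float
    sex: int  # female = 1, male = 0
    assessments: list[Assessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise DomainError(f"sex must be 0 (male) or 1 (female), got {self.sex}")
        self.assessments = sorted(self.assessments, key=lambda a: a.t)
        for a in self.assessments:
            if a.score > self.polarity.scale_max:
                raise DomainError(
                    f"{self.subject_id}: score {a.score} exceeds "
                    f"{self.polarity.scale} maximum {self.polarity.scale_max}"
                )
        if self.assessments and self.assessments[0].score == 0:
            raise DomainError(
                f"{self.subject_id}: onset score 0 — no acute episode to enrol"
            )

    @property
    def scores(self) -> list[int]:
        return [a.score for a in self.assessments]


def improvement(score0: float, score_t: float) -> float:
    """Fractional symptom improvement relative to episode onset.

    ``(score0 - score_t) / score0`` — 0 at onset, 1 at full resolution.
    """
    if score0 <= 0:
        raise DomainError("onset score must be positive to define improvement")
    if score_t > score0:
        raise DomainError(
            f"score {score_t} exceeds onset score {score0}: monotonicity violated"
        )
    if score_t < 0:
        raise DomainError("scale totals cannot be negative")
    return (score0 - score_t) / score0


def baseline_severity(score0: float, polarity: Polarity) -> float:
    """Onset score divided by the scale maximum (60 YMRS, 52 HDRS)."""
    if not 0 <= score0 <= polarity.scale_max:
        raise DomainError(
            f"score {score0} outside [0, {polarity.scale_max}] for {polarity.scale}"
        )
    return score0 / polarity.scale_max


def standardize_age(ages: Sequence[float]) -> np.ndarray:
    """Standardize ages to mean 0, sd 1 (sample sd, n-1 denominator)."""
    arr = np.asarray(ages, dtype=float)
    if arr.size < 2:
        raise ZeroVarianceError("need at least two subjects to standardize age")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("ages are constant; standardization undefined")
    return (arr - arr.mean()) / sd


def medication_count(flags: Mapping[str, bool]) -> int:
    """Number of HRV-relevant medication classes switched on."""
    unknown = set(flags) - set(MEDICATION_CLASSES)
    if unknown:
        raise SchemaError(f"unknown medication classes: {sorted(unknown)}")
    return int(sum(bool(v) for v in flags.values()))


#: machine-readable exclusion reasons
TOO_FEW_ASSESSMENTS = "too_few_assessments"
NON_MONOTONIC = "non_monotonic"


def apply_inclusion_filters(
    subjects: Iterable[Subject],
    require_hrv: bool = True,
) -> tuple[list[Subject], list[tuple[Subject, str]]]:
    """Partition subjects into (included, excluded-with-reason).

    Inclusion requires >= 3 assessments (with a night lnRMSSD attached when
    ``require_hrv``) and strictly decreasing scale totals across successive
    sessions. Idempotent: included subjects pass the filters again unchanged.
    """
    included: list[Subject] = []
    excluded: list[tuple[Subject, str]] = []
    for s in subjects:
        usable = [
            a for a in s.assessments if (a.ln_rmssd is not None or not require_hrv)
        ]
        if len(usable) < 3:
            excluded.append((s, TOO_FEW_ASSESSMENTS))
            continue
        scores = [a.score for a in usable]
        if any(b >= a for a, b in zip(scores, scores[1:])):
            excluded.append((s, NON_MONOTONIC))
            continue
        included.append(s)
    return included, excluded


def build_table(
    subjects: Sequence[Subject],
    night_hrv: Mapping[tuple[str, int], float] | None = None,
) -> pd.DataFrame:
    """Assemble the long-format model table (one row per assessment).

    ``night_hrv`` maps ``(subject_id, t)`` to ln_rmssd; when omitted, each
    assessment must already carry its ``ln_rmssd`` (as produced by the
    synthetic generator). Age is standardized over the supplied subjects.
    """
    if len(subjects) < 2:
        raise DomainError("need at least two subjects to build the model table")
    a_std = standardize_age([s.age for s in subjects])
    rows = []
    for i, s in enumerate(subjects):
        score0 = s.assessments[0].score
        b = baseline_severity(score0, s.polarity)
        for a in s.assessments:
            if night_hrv is not None:
                key = (s.subject_id, a.t)
                if key not in night_hrv:
                    raise LinkageError(
                        f"no night HRV for subject {s.subject_id}, assessment t={a.t}"
                    )
                y = night_hrv[key]
            else:
                if a.ln_rmssd is None:
                    raise LinkageError(
                        f"assessment {s.subject_id} t={a.t} has no ln_rmssd attached"
                    )
                y = a.ln_rmssd
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "subject_index": i,
                    "t": a.t,
                    "ln_rmssd": float(y),
                    "I": improvement(score0, a.score),
                    "M": medication_count(a.medication_flags),
                    "A_std": float(a_std[i]),
                    "S": int(s.sex),
                    "B": b,
                    "polarity": s.polarity.value,
                    "polarity_index": 0 if s.polarity is Polarity.MANIA else 1,
                }
            )
    return pd.DataFrame(rows)


def read_assessments_csv(path) -> list[Subject]:
    """Read the assessments table written by the synthetic generator."""
    df = pd.read_csv(path, parse_dates=["datetime"])
    required = {"subject_id", "polarity", "t", "score", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"assessments CSV missing columns: {sorted(missing)}")
    med_cols = [c for c in df.columns if c in MEDICATION_CLASSES]
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("t")
        first = grp.iloc[0]
        assessments = [
            Assessment(
                subject_id=str(sid),
                t=int(r["t"]),
                score=int(r["score"]),
                datetime=r["datetime"].to_pydatetime() if "datetime" in grp else None,
                medication_flags={c: bool(r[c]) for c in med_cols},
            )
            for _, r in grp.iterrows()
        ]
        subjects.append(
            Subject(
                subject_id=str(sid),
                polarity=Polarity(first["polarity"]),
                age=float(first["age"]),
                sex=int(first["sex"]),
                assessments=assessments,
            )
        )
    return subjects


def write_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
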