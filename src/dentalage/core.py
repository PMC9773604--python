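"""Core vocabulary for staged dental development.

Dental age (DA) estimation in children works from the seven permanent teeth of
the left mandibular quadrant (FDI 31-37, third molar excluded), each assigned
one of the eight Demirjian calcification stages A-H, where A marks the first
calcified points and H the closed apical foramen (a fully mature root). This
module holds the shared domain types — stages, teeth, subjects, datasets, the
two estimator reference tables — and the small date/count primitives every
estimator builds on.

Stage ``N`` (no visible calcification, ordered below A) is an extension beyond
the classical A-H ladder so that very immature teeth are representable; every
estimator treats it simply as "not yet mature".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Iterator, Mapping

import pandas as pd

#: Ordered stage codes, most immature first.  Index 0 (``N``) is pre-A; index
#: 8 (``H``) is the unique terminal stage (root complete).
STAGES: tuple[str, ...] = ("N", "A", "B", "C", "D", "E", "F", "G", "H")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
MATURE_STAGE = "H"

#: FDI codes of the left mandibular permanent teeth, central incisor (31)
#: through second molar (37).  38 (third molar) is always rejected.
TOOTH_IDS: tuple[int, ...] = (31, 32, 33, 34, 35, 36, 37)

#: Recognised estimation methods.
METHODS: tuple[str, ...] = ("atlas", "willems", "quick")

DAYS_PER_YEAR = 365.25

#: Default study age window: subjects aged 10.00-16.99 years, i.e. the seven
#: one-year brackets 10..16.
DEFAULT_AGE_RANGE: tuple[float, float] = (10.0, 17.0)


class DentalAgeError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(DentalAgeError, ValueError):
    """A record, table or atlas violates a structural invariant."""


class CoverageError(DentalAgeError, LookupError):
    """A lookup key (scoring-table entry, group minuend) is not covered."""


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, Sex):
            return value
        text = str(value).strip().upper()
        if text in ("M", "MALE", "BOY"):
            return cls.MALE
        if text in ("F", "FEMALE", "GIRL"):
            return cls.FEMALE
        raise ValidationError(f"unrecognised sex code {value!r} (expected M/F)")


def stage_index(code: str) -> int:
    """Ordinal index of a stage code: N=0, A=1, ..., H=8."""
    try:
        return STAGE_INDEX[code]
    except KeyError:
        raise ValidationError(
            f"unrecognised stage code {code!r} (expected one of {'/'.join(STAGES)})"
        ) from None


def validate_tooth(fdi_code: int) -> int:
    if fdi_code not in TOOTH_IDS:
        raise ValidationError(
            f"invalid tooth {fdi_code!r}: expected FDI 31-37 (third molar 38 excluded)"
        )
    return fdi_code


def chronological_age(birth_date: date, exam_date: date) -> float:
    """Chronological age in decimal years at the radiograph date.

    The day count from birth to examination is divided by 365.25 and rounded
    (half to even) to two decimals, the precision all downstream ages carry.
    """
    if exam_date < birth_date:
        raise ValidationError(
            f"exam date {exam_date} precedes birth date {birth_date}"
        )
    days = (exam_date - birth_date).days
    return round(days / DAYS_PER_YEAR, 2)


@dataclass(frozen=True)
class SubjectRecord:
    """One child: sex, chronological age, and a stage per quadrant tooth.

    ``stages`` must cover all seven teeth of :data:`TOOTH_IDS`; a record with
    a missing tooth is rejected outright (unilateral loss is not
    representable).  ``observer_id`` distinguishes repeat-rating channels of
    the same subject for reliability analysis.
    """

    subject_id: str
    sex: Sex
    ca_years: float
    stages: Mapping[int, str]
    observer_id: str = "obs1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if not (isinstance(self.ca_years, (int, float)) and math.isfinite(self.ca_years)):
            raise ValidationError(f"ca_years {self.ca_years!r} is not a finite number")
        if self.ca_years < 0:
            raise ValidationError(f"ca_years must be >= 0, got {self.ca_years}")
        got = set(self.stages)
        expected = set(TOOTH_IDS)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValidationError(
                f"subject {self.subject_id!r}: stages must cover teeth "
                f"{list(TOOTH_IDS)}; missing {missing}, unexpected {extra}"
            )
        for tooth, code in self.stages.items():
            stage_index(code)
        object.__setattr__(self, "stages", dict(self.stages))


def immature_count(record: "SubjectRecord | Mapping[int, str]") -> int:
    """Number of quadrant teeth with incomplete roots (stage != H), 0-7.

    This count is the subtrahend of the quick method: one immature tooth is
    read as roughly one year short of a fully developed quadrant.
    """
    stages = record.stages if isinstance(record, SubjectRecord) else record
    return sum(1 for t in TOOTH_IDS if stages[t] != MATURE_STAGE)


def age_bracket(
    ca_years: float, age_range: tuple[float, float] = DEFAULT_AGE_RANGE
) -> int:
    """Whole-year age bracket (floor of age); 10..16 over the study range."""
    lo, hi = age_range
    if not (lo <= ca_years < hi):
        raise ValidationError(
            f"age {ca_years} outside configured study range [{lo}, {hi})"
        )
    return int(math.floor(ca_years))


@dataclass(frozen=True)
class Estimate:
    """A dental-age estimate for one subject by one method.

    ``error_years`` follows the forensic sign convention CA − DA: a positive
    value means the method underestimated the child's age.
    """

    subject_id: str
    method: str
    da_years: float
    error_years: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )


@dataclass
class Dataset:
    """An ordered collection of subject records with provenance metadata.

    ``subject_id`` must be unique within each observer channel; the same
    subject may appear once per observer (repeat ratings).
    """

    records: list[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.subject_id, rec.observer_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate subject {rec.subject_id!r} in observer "
                    f"channel {rec.observer_id!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def observers(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.observer_id not in out:
                out.append(rec.observer_id)
        return out

    def channel(self, observer_id: str) -> "Dataset":
        """Sub-dataset of a single observer channel."""
        recs = [r for r in self.records if r.observer_id == observer_id]
        prov = dict(self.provenance, observer_id=observer_id)
        return Dataset(recs, prov)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "sex": r.sex.value,
                "ca_years": r.ca_years,
                **{f"s{t}": r.stages[t] for t in TOOTH_IDS},
                "observer_id": r.observer_id,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["subject_id", "sex", "ca_years"]
            + [f"s{t}" for t in TOOTH_IDS]
            + ["observer_id"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "Dataset":
        records = [
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                sex=Sex.parse(row["sex"]),
                ca_years=round(float(row["ca_years"]), 2),
                stages={t: str(row[f"s{t}"]) for t in TOOTH_IDS},
                observer_id=str(row.get("observer_id", "obs1")),
            )
            for _, row in df.iterrows()
        ]
        return cls(records, provenance or {})


@dataclass
class ScoringTable:
    """Willems-style maturity scores: (sex, tooth, stage) → score in years.

    The seven per-tooth scores of a subject sum directly to the dental age.
    Tables cover stages A-H only (the published tables have no pre-A entry);
    a lookup outside the covered keys is a :class:`CoverageError`, never a
    silent default.  Within each (sex, tooth) the table must be complete
    across A-H.
    """

    entries: dict[tuple[Sex, int, str], float]

    def __post_init__(self) -> None:
        clean: dict[tuple[Sex, int, str], float] = {}
        for (sex, tooth, stage), score in self.entries.items():
            sex = Sex.parse(sex)
            validate_tooth(tooth)
            if stage not in STAGES[1:]:
                raise ValidationError(
                    f"scoring table stage must be A-H, got {stage!r}"
                )
            score = float(score)
            if score < 0:
                raise ValidationError(
                    f"negative score {score} for ({sex.value}, {tooth}, {stage})"
                )
            clean[(sex, tooth, stage)] = score
        covered = {(s, t) for (s, t, _) in clean}
        for sex, tooth in covered:
            have = {st for (s, t, st) in clean if (s, t) == (sex, tooth)}
            missing = [st for st in STAGES[1:] if st not in have]
            if missing:
                raise ValidationError(
                    f"scoring table incomplete for ({sex.value}, {tooth}): "
                    f"missing stages {missing}"
                )
        self.entries = clean

    def score(self, sex: Sex, tooth: int, stage: str) -> float:
        key = (Sex.parse(sex), validate_tooth(tooth), stage)
        try:
            return self.entries[key]
        except KeyError:
            raise CoverageError(
                f"scoring table has no entry for sex={key[0].value}, "
                f"tooth={tooth}, stage={stage!r}"
            ) from None

    def is_monotone(self) -> bool:
        """True if scores are non-decreasing in stage order per (sex, tooth)."""
        for sex, tooth in {(s, t) for (s, t, _) in self.entries}:
            scores = [self.entries[(sex, tooth, st)] for st in STAGES[1:]]
            if any(b < a for a, b in zip(scores, scores[1:])):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex.value, "fdi": tooth, "stage": stage, "score_years": score}
            for (sex, tooth, stage), score in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1], STAGE_INDEX[kv[0][2]])
            )
        ]
        return pd.DataFrame(rows, columns=["sex", "fdi", "stage", "score_years"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoringTable":
        entries = {
            (Sex.parse(row["sex"]), int(row["fdi"]), str(row["stage"])): float(
                row["score_years"]
            )
            for _, row in df.iterrows()
        }
        return cls(entries)


@dataclass
class Atlas:
    """A stage-schedule atlas: reference ages with expected stages per tooth.

    Each grid point plays the role of one reference depiction of the London
    Atlas; matching a subject's stage vector against the grid and reading off
    the best reference age is the atlas estimate.  A 0.5-year ``step`` grid
    realises half-year "in-between" references.
    """

    grid: list[tuple[float, dict[int, str]]]
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValidationError("atlas grid must be non-empty")
        if self.step <= 0:
            raise ValidationError("atlas step must be positive")
        ages = [age for age, _ in self.grid]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError("atlas reference ages must be strictly increasing")
        for age, expected in self.grid:
            if set(expected) != set(TOOTH_IDS):
                raise ValidationError(
                    f"atlas column at age {age} must cover teeth {list(TOOTH_IDS)}"
                )
            for code in expected.values():
                stage_index(code)
        for tooth in TOOTH_IDS:
            idx = [stage_index(expected[tooth]) for _, expected in self.grid]
            if any(b < a for a, b in zip(idx, idx[1:])):
                raise ValidationError(
                    f"atlas stages for tooth {tooth} must be non-decreasing in age"
                )

    @property
    def ref_ages(self) -> list[float]:
        return [age for age, _ in self.grid]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref_age": age, **{f"s{t}": expected[t] for t in TOOTH_IDS}}
            for age, expected in self.grid
        ]
        return pd.DataFrame(rows, columns=["ref_age"] + [f"s{t}" for t in TOOTH_IDS])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, step: float | None = None) -> "Atlas":
        grid = [
            (float(row["ref_age"]), {t: str(row[f"s{t}"]) for t in TOOTH_IDS})
            for _, row in df.iterrows()
        ]
        if step is None:
            ages = [a for a, _ in grid]
            diffs = {round(b - a, 6) for a, b in zip(ages, ages[1:])}
            step = diffs.pop() if len(diffs) == 1 else 1.0
        return cls(grid, step=step)
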