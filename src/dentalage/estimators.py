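"""The three dental-age estimators and the quick-method minuend correction.

* Quick method: DA = minuend − (number of root-incomplete teeth in the left
  mandibular quadrant).  The default minuend of 16 years encodes the rule of
  thumb that the quadrant (third molar excluded) is fully developed by 16.
* Willems-style scoring: each tooth's stage is converted to a sex-specific
  maturity score in years and the seven scores sum to DA.
* Atlas matching: the subject's stage vector is compared against a schedule
  of reference ages and the best-matching reference age is DA.

The minuend correction is a one-parameter (per group) location fit: since the
quick-method error is CA − DA = CA + count − M, the minuend that zeroes the
mean error of a group is the group mean of CA + count.  It is exposed both as
a statsmodels-style model/results pair (:class:`QuickMinuendModel`) and as the
convenience :func:`fit_quick_minuend`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_AGE_RANGE,
    STAGES,
    TOOTH_IDS,
    Atlas,
    CoverageError,
    Dataset,
    Estimate,
    ScoringTable,
    Sex,
    SubjectRecord,
    ValidationError,
    age_bracket,
    immature_count,
    stage_index,
)
from .simulate import MaturationModel

DEFAULT_MINUEND = 16.0
GROUPINGS = ("overall", "by_sex", "by_sex_and_bracket")


@dataclass(frozen=True)
class QuickParams:
    """Quick-method parameters: a global or group-specific minuend.

    ``grouping`` selects how the minuend is looked up: a single ``minuend``
    (overall), per sex, or per (sex, whole-year age bracket).  Group keys are
    ``Sex`` values or ``(Sex, bracket)`` tuples.  A record whose group is not
    covered raises :class:`~dentalage.core.CoverageError`.
    """

    minuend: float = DEFAULT_MINUEND
    grouping: str = "overall"
    group_minuends: Mapping | None = None
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise ValidationError(
                f"unknown grouping {self.grouping!r}; expected one of {GROUPINGS}"
            )
        if self.minuend <= 0:
            raise ValidationError("minuend must be positive")
        if self.grouping != "overall" and not self.group_minuends:
            raise ValidationError(
                f"grouping {self.grouping!r} requires group_minuends"
            )
        if self.group_minuends is not None:
            object.__setattr__(self, "group_minuends", dict(self.group_minuends))

    def minuend_for(self, record: SubjectRecord) -> float:
        if self.grouping == "overall":
            return self.minuend
        if self.grouping == "by_sex":
            key = record.sex
        else:
            key = (record.sex, age_bracket(record.ca_years, self.age_range))
        try:
            return self.group_minuends[key]
        except KeyError:
            raise CoverageError(
                f"no minuend configured for group {key!r} "
                f"(grouping={self.grouping!r})"
            ) from None


def quick_estimate(
    record: SubjectRecord, params: QuickParams | None = None
) -> Estimate:
    """Quick subtraction estimate: minuend minus the immature-tooth count."""
    params = params or QuickParams()
    da = params.minuend_for(record) - immature_count(record)
    return Estimate(
        subject_id=record.subject_id,
        method="quick",
        da_years=da,
        error_years=record.ca_years - da,
    )


def _quick_frame(dataset: Dataset, age_range: tuple[float, float]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "bracket": age_bracket(rec.ca_years, age_range),
            "ca_years": rec.ca_years,
            "count": immature_count(rec),
        }
        for rec in dataset
    ]
    df = pd.DataFrame(rows)
    df["target"] = df["ca_years"] + df["count"]
    return df


class QuickMinuendModel:
    """Minuend-correction model for the quick method.

    For each group g the corrected minuend is the value M̂_g that makes the
    quick method's mean error on g vanish:

        error_i = CA_i − (M − count_i)   ⇒   M̂_g = mean_g(CA_i + count_i).

    ``grouping`` is one of ``overall``, ``by_sex``, ``by_sex_and_bracket``.
    Under ``by_sex`` both sexes must be present; under ``by_sex_and_bracket``
    every sex × observed-bracket cell must be non-empty.
    """

    def __init__(
        self,
        dataset: Dataset,
        grouping: str = "overall",
        age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    ):
        if grouping not in GROUPINGS:
            raise ValidationError(
                f"unknown grouping {grouping!r}; expected one of {GROUPINGS}"
            )
        if len(dataset) == 0:
            raise ValidationError("cannot fit a minuend on an empty dataset")
        self.grouping = grouping
        self.age_range = age_range
        self.data = _quick_frame(dataset, age_range)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        grouping: str = "overall",
        age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    ) -> "QuickMinuendModel":
        """Build from a dataset-shaped frame (columns sex, ca_years, s31..s37)."""
        return cls(Dataset.from_frame(df), grouping=grouping, age_range=age_range)

    def _group_keys(self) -> pd.Series:
        if self.grouping == "overall":
            return pd.Series(["overall"] * len(self.data), index=self.data.index)
        if self.grouping == "by_sex":
            return self.data["sex"]
        return pd.Series(
            list(zip(self.data["sex"], self.data["bracket"])), index=self.data.index
        )

    def _required_groups(self) -> list:
        if self.grouping == "overall":
            return ["overall"]
        if self.grouping == "by_sex":
            return [Sex.MALE, Sex.FEMALE]
        brackets = sorted(self.data["bracket"].unique())
        return [(sex, b) for sex in (Sex.MALE, Sex.FEMALE) for b in brackets]

    def fit(self) -> "QuickMinuendResults":
        keys = self._group_keys()
        by_group: dict = {}
        for g, sub in self.data.groupby(keys, sort=False)["target"]:
            by_group[g] = sub.to_numpy(dtype=float)
        params: dict = {}
        group_sd: dict = {}
        nobs: dict = {}
        for g in self._required_groups():
            values = by_group.get(g)
            if values is None or len(values) == 0:
                raise ValidationError(
                    f"empty group {_group_label(g)!r} under grouping {self.grouping!r}"
                )
            params[g] = float(np.mean(values))
            group_sd[g] = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
            nobs[g] = len(values)
        return QuickMinuendResults(
            model=self, params=params, group_sd=group_sd, nobs_per_group=nobs
        )


class QuickMinuendResults:
    """Fitted group minuends with their uncertainties.

    ``params`` holds M̂ per group; ``bse`` the standard error of each group
    mean; ``conf_int`` the normal-theory t confidence intervals.  By
    construction the corrected quick method has exactly zero mean error on
    the fitting data within every group.
    """

    def __init__(self, model, params: dict, group_sd: dict, nobs_per_group: dict):
        self.model = model
        self.params = params
        self.group_sd = group_sd
        self.nobs_per_group = nobs_per_group
        self.nobs = int(sum(nobs_per_group.values()))

    @property
    def bse(self) -> dict:
        return {
            g: self.group_sd[g] / math.sqrt(n)
            for g, n in self.nobs_per_group.items()
        }

    def conf_int(self, alpha: float = 0.05) -> dict:
        """Per-group t confidence interval for the fitted minuend."""
        out: dict = {}
        for g, m in self.params.items():
            n = self.nobs_per_group[g]
            sd = self.group_sd[g]
            if n < 2 or not math.isfinite(sd):
                out[g] = (float("nan"), float("nan"))
                continue
            half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / math.sqrt(n)
            out[g] = (m - half, m + half)
        return out

    def to_quick_params(self) -> QuickParams:
        if self.model.grouping == "overall":
            return QuickParams(
                minuend=self.params["overall"],
                age_range=self.model.age_range,
            )
        return QuickParams(
            minuend=DEFAULT_MINUEND,
            grouping=self.model.grouping,
            group_minuends=dict(self.params),
            age_range=self.model.age_range,
        )

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        bse = self.bse
        return pd.DataFrame(
            {
                "group": [_group_label(g) for g in self.params],
                "minuend": list(self.params.values()),
                "se": [bse[g] for g in self.params],
                "n": [self.nobs_per_group[g] for g in self.params],
                "ci_low": [ci[g][0] for g in self.params],
                "ci_high": [ci[g][1] for g in self.params],
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Quick-method minuend correction",
            f"  grouping: {self.model.grouping}    n = {self.nobs}",
            "",
            df.to_string(
                index=False,
                float_format=lambda x: f"{x:8.4f}" if math.isfinite(x) else "     nan",
            ),
            "",
            "Corrected minuend M per group zeroes the group's mean error",
            "(M = group mean of CA + immature-tooth count).",
        ]
        return "\n".join(lines)


def _group_label(g) -> str:
    if isinstance(g, Sex):
        return g.value
    if isinstance(g, tuple):
        return "/".join(_group_label(x) for x in g)
    return str(g)


def fit_quick_minuend(
    dataset: Dataset,
    grouping: str = "overall",
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> QuickParams:
    """Fit corrected quick-method minuends; see :class:`QuickMinuendModel`."""
    return (
        QuickMinuendModel(dataset, grouping=grouping, age_range=age_range)
        .fit()
        .to_quick_params()
    )


def willems_estimate(record: SubjectRecord, table: ScoringTable) -> Estimate:
    """Willems-style estimate: the seven per-tooth maturity scores summed."""
    da = sum(
        table.score(record.sex, tooth, record.stages[tooth]) for tooth in TOOTH_IDS
    )
    return Estimate(
        subject_id=record.subject_id,
        method="willems",
        da_years=da,
        error_years=record.ca_years - da,
    )


def atlas_distance(stages: Mapping[int, str], expected: Mapping[int, str]) -> int:
    """L1 distance between two stage maps on the stage-ordinal scale."""
    return sum(
        abs(stage_index(stages[t]) - stage_index(expected[t])) for t in TOOTH_IDS
    )


def atlas_estimate(record: SubjectRecord, atlas: Atlas) -> Estimate:
    """Atlas estimate: reference age of the best-matching schedule column.

    Match quality is the L1 distance between the subject's stage vector and
    each column's expected stages, on the ordinal N..H scale.  Ties take the
    arithmetic mean of the tied reference ages (directionally unbiased; a
    unique exact match is returned as-is).
    """
    dists = [atlas_distance(record.stages, expected) for _, expected in atlas.grid]
    best = min(dists)
    tied = [age for (age, _), d in zip(atlas.grid, dists) if d == best]
    da = sum(tied) / len(tied)
    return Estimate(
        subject_id=record.subject_id,
        method="atlas",
        da_years=da,
        error_years=record.ca_years - da,
    )


def build_atlas_from_model(
    model: MaturationModel,
    sex: Sex,
    step: float = 0.5,
    age_range: tuple[float, float] = (9.0, 17.0),
) -> Atlas:
    """Derive a stage-schedule atlas from a maturation model.

    Each grid age's expected stages are the model's zero-noise stages at that
    age.  A 0.5-year step realises half-year in-between references.
    """
    lo, hi = age_range
    if step <= 0:
        raise ValidationError("atlas step must be positive")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValidationError(
            f"step {step} does not divide the age range [{lo}, {hi}]"
        )
    sex = Sex.parse(sex)
    grid = []
    for i in range(int(round(n_steps)) + 1):
        age = round(lo + i * step, 10)
        expected = {t: model.stage_at(sex, t, age) for t in TOOTH_IDS}
        grid.append((age, expected))
    return Atlas(grid, step=step)


def build_scoring_table_from_model(
    model: MaturationModel,
    terminal_width: float | None = None,
) -> ScoringTable:
    """Derive a synthetic Willems-style scoring table from a maturation model.

    The published Willems tables are not reproduced here; this builds a
    monotone stand-in from the generative model itself.  A tooth observed at
    stage s is typically seen between τ(s) and τ(next stage), so its score is
    the midpoint of that occupancy window divided by 7 — making the seven
    scores sum to roughly the child's age when every tooth sits at its
    expected stage.  Stage H, which has no upper threshold, uses a window of
    ``terminal_width`` (default: the model's G→H gap).
    """
    entries: dict[tuple[Sex, int, str], float] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        for tooth in TOOTH_IDS:
            ladder = model.stage_ladder(sex, tooth)
            width = (
                terminal_width
                if terminal_width is not None
                else ladder[-1] - ladder[-2]
            )
            for i, stage in enumerate(STAGES[1:]):
                lo = ladder[i]
                hi = ladder[i + 1] if i + 1 < len(ladder) else ladder[i] + width
                entries[(sex, tooth, stage)] = max((lo + hi) / 2.0, 0.0) / 7.0
    return ScoringTable(entries)


def estimate_dataset(
    dataset: Dataset,
    methods: Sequence[str] = ("quick", "willems", "atlas"),
    quick_params: QuickParams | None = None,
    scoring_table: ScoringTable | None = None,
    atlas: "Atlas | Mapping[Sex, Atlas] | None" = None,
) -> list[Estimate]:
    """Run one or more estimators over every record of a dataset.

    ``atlas`` may be a single atlas applied to everyone or a per-sex mapping
    (model-derived atlases are sex-specific).  Estimates come back in long
    form, one per (subject, method).
    """
    estimates: list[Estimate] = []
    for method in methods:
        if method == "quick":
            for rec in dataset:
                estimates.append(quick_estimate(rec, quick_params))
        elif method == "willems":
            if scoring_table is None:
                raise ValidationError("willems estimation requires a scoring table")
            for rec in dataset:
                estimates.append(willems_estimate(rec, scoring_table))
        elif method == "atlas":
            if atlas is None:
                raise ValidationError("atlas estimation requires an atlas")
            for rec in dataset:
                a = atlas[rec.sex] if isinstance(atlas, Mapping) else atlas
                estimates.append(atlas_estimate(rec, a))
        else:
            raise ValidationError(f"unknown estimation method {method!r}")
    return estimates


def estimates_to_frame(estimates: Iterable[Estimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "method": e.method,
                "da_years": e.da_years,
                "error_years": e.error_years,
            }
            for e in estimates
        ],
        columns=["subject_id", "method", "da_years", "error_years"],
    )
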