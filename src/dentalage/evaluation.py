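"""Accuracy, precision and reliability statistics for dental-age methods.

The method-comparison protocol: per stratum (method × whole-year age bracket
× sex, or any subset), the mean error ME = mean(CA − DA) with sample SD, the
bias-independent mean absolute error MAE with SD, a two-sided paired t-test
of CA vs DA with a 95% CI on the mean difference, and the percentage of
subjects whose absolute error falls under 1 year, between 1 and 2 years, or
at 2 years and beyond.  Sex differences in error are compared with Welch's
independent-samples t-test, and rating reliability with the intraclass
correlation coefficient ICC(2,1) (two-way random effects, absolute
agreement, single rater).

Sign convention throughout: error = CA − DA, so a positive value means the
method underestimated the child's age.  All SDs use the n−1 denominator.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_AGE_RANGE,
    Dataset,
    DentalAgeError,
    Estimate,
    ValidationError,
    age_bracket,
)

STRATIFIERS = ("method", "bracket", "sex")


def _as_array(errors: Iterable[float], what: str) -> np.ndarray:
    arr = np.asarray(list(errors), dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{what} requires at least one value")
    return arr


def mean_error(errors: Iterable[float]) -> tuple[float, float]:
    """Mean error and its sample SD; SD is NaN for a single value."""
    arr = _as_array(errors, "mean_error")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd


def mean_absolute_error(errors: Iterable[float]) -> tuple[float, float]:
    """Mean of |error| and its sample SD; SD is NaN for a single value."""
    arr = np.abs(_as_array(errors, "mean_absolute_error"))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd


class PairedTTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    ci_low: float
    ci_high: float


class IndependentTTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def paired_t_test(
    ca: Sequence[float], da: Sequence[float], alpha: float = 0.05
) -> PairedTTestResult:
    """Two-sided paired t-test of CA vs DA with a CI on the mean difference.

    Degenerate inputs: a zero-variance difference vector gives t = 0, p = 1
    when the mean difference is also zero, and an infinite t with p = 0 (and
    a warning) otherwise.
    """
    ca_arr = np.asarray(ca, dtype=float)
    da_arr = np.asarray(da, dtype=float)
    if ca_arr.shape != da_arr.shape:
        raise ValidationError("paired t-test requires equal-length vectors")
    if ca_arr.size < 2:
        raise ValidationError("paired t-test requires at least two pairs")
    d = ca_arr - da_arr
    n = d.size
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTTestResult(0.0, n - 1, 1.0, 0.0, 0.0)
        warnings.warn(
            "paired t-test: zero-variance differences with non-zero mean "
            "(degenerate, infinite t)",
            stacklevel=2,
        )
        return PairedTTestResult(
            math.copysign(math.inf, mean), n - 1, 0.0, mean, mean
        )
    res = stats.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(1 - alpha)
    return PairedTTestResult(
        float(res.statistic), n - 1, float(res.pvalue), float(ci.low), float(ci.high)
    )


def independent_t_test(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    equal_var: bool = False,
) -> IndependentTTestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("independent t-test requires n >= 2 per group")
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return IndependentTTestResult(0.0, float(df), 1.0)
        warnings.warn(
            "independent t-test: both groups have zero variance with "
            "different means (degenerate, infinite t)",
            stacklevel=2,
        )
        return IndependentTTestResult(
            math.copysign(math.inf, a.mean() - b.mean()), float(df), 0.0
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return IndependentTTestResult(
        float(res.statistic), float(res.df), float(res.pvalue)
    )


class ErrorBands(NamedTuple):
    pct_under_1: float
    pct_1_to_2: float
    pct_2_plus: float


def error_band_frequencies(errors: Iterable[float]) -> ErrorBands:
    """Percentages of |error| in [0,1), [1,2) and [2,∞), to one decimal.

    Half-open bands make the partition exhaustive and exclusive: an error of
    exactly one year counts in the 1-2 year band.
    """
    arr = np.abs(_as_array(errors, "error_band_frequencies"))
    n = arr.size
    under_1 = float(np.sum(arr < 1.0)) / n * 100.0
    one_two = float(np.sum((arr >= 1.0) & (arr < 2.0))) / n * 100.0
    two_plus = float(np.sum(arr >= 2.0)) / n * 100.0
    return ErrorBands(round(under_1, 1), round(one_two, 1), round(two_plus, 1))


class ICCResult(NamedTuple):
    value: float
    ms_subjects: float
    ms_raters: float
    ms_error: float
    n_subjects: int
    n_raters: int


def icc_agreement(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects × raters matrix (dental ages or stage indices)
    with no missing cells.  From the two-way ANOVA mean squares MS_R (rows/
    subjects), MS_C (columns/raters) and MS_E (residual):

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n)

    Identical rating channels give exactly 1.  Zero between-subject variance
    leaves the coefficient undefined (NaN, with a warning).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects × raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("ICC requires at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValidationError("ICC requires a complete matrix (no missing cells)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0.0:
        warnings.warn(
            "ICC undefined: no between-subject variance", stacklevel=2
        )
        return ICCResult(float("nan"), ms_r, ms_c, ms_e, n, k)
    icc = (ms_r - ms_e) / denom
    return ICCResult(float(icc), float(ms_r), float(ms_c), float(ms_e), n, k)


def _group_stats_row(ca: np.ndarray, da: np.ndarray) -> dict:
    errors = ca - da
    me, me_sd = mean_error(errors)
    mae, mae_sd = mean_absolute_error(errors)
    if errors.size >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = paired_t_test(ca, da)
        t_stat, df, p, ci_lo, ci_hi = t
    else:
        t_stat = df = p = ci_lo = ci_hi = float("nan")
    bands = error_band_frequencies(errors)
    return {
        "n": int(errors.size),
        "me": me,
        "me_sd": me_sd,
        "mae": mae,
        "mae_sd": mae_sd,
        "t": t_stat,
        "df": df,
        "p": p,
        "ci_low": ci_lo,
        "ci_high": ci_hi,
        "pct_under_1": bands.pct_under_1,
        "pct_1_to_2": bands.pct_1_to_2,
        "pct_2_plus": bands.pct_2_plus,
    }


NO_CORRECTION_NOTE = (
    "Note: p-values are reported per stratum without multiple-testing "
    "correction across the bracket × sex × method grid."
)


@dataclass
class EvaluationReport:
    """Stratified accuracy/precision report for one or more methods.

    ``stats`` has one row per non-empty stratum; ``overall`` one row per
    method (stratifier columns set to ``all``); ``sex_comparison`` the
    per-method Welch test of male vs female errors (empty if a sex has
    fewer than two subjects).
    """

    stats: pd.DataFrame
    overall: pd.DataFrame
    sex_comparison: pd.DataFrame
    stratify_by: tuple[str, ...]
    footer: str = NO_CORRECTION_NOTE

    def summary(self, float_fmt: str = "%.3f") -> str:
        parts = [
            "Dental age estimation — accuracy and precision report",
            f"Stratified by: {', '.join(self.stratify_by) or '(none)'}",
            "Error = CA − DA (positive = underestimate); SD uses n−1.",
            "",
            "Overall by method:",
            self.overall.to_string(index=False, float_format=lambda x: float_fmt % x),
            "",
            "Per stratum:",
            self.stats.to_string(index=False, float_format=lambda x: float_fmt % x),
        ]
        if len(self.sex_comparison):
            parts += [
                "",
                "Sex comparison of errors (Welch t-test) per method:",
                self.sex_comparison.to_string(
                    index=False, float_format=lambda x: float_fmt % x
                ),
            ]
        parts += ["", self.footer]
        return "\n".join(parts)

    def to_json(self) -> str:
        payload = {
            "stratify_by": list(self.stratify_by),
            "overall": self.overall.to_dict(orient="records"),
            "strata": self.stats.to_dict(orient="records"),
            "sex_comparison": self.sex_comparison.to_dict(orient="records"),
            "footer": self.footer,
        }

        def clean(obj):
            if isinstance(obj, float) and not math.isfinite(obj):
                return None
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj

        return json.dumps(clean(payload), indent=2)


def evaluate(
    dataset: Dataset,
    estimates: Iterable[Estimate],
    stratify_by: Sequence[str] = ("method", "bracket", "sex"),
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> EvaluationReport:
    """Join estimates to their subjects and compute the full report.

    Every estimate must match a dataset record by subject id (an orphan
    estimate is an error); if the dataset holds several observer channels,
    evaluate one channel at a time (``dataset.channel(...)``).
    """
    for s in stratify_by:
        if s not in STRATIFIERS:
            raise ValidationError(
                f"unknown stratifier {s!r}; expected a subset of {STRATIFIERS}"
            )
    observers = dataset.observers()
    if len(observers) > 1:
        raise ValidationError(
            f"dataset has several observer channels {observers}; "
            "evaluate one channel at a time"
        )
    by_id = {rec.subject_id: rec for rec in dataset}
    rows = []
    for est in estimates:
        rec = by_id.get(est.subject_id)
        if rec is None:
            raise DentalAgeError(
                f"estimate for unknown subject {est.subject_id!r} (join error)"
            )
        rows.append(
            {
                "subject_id": est.subject_id,
                "method": est.method,
                "sex": rec.sex.value,
                "bracket": age_bracket(rec.ca_years, age_range),
                "ca_years": rec.ca_years,
                "da_years": est.da_years,
            }
        )
    if not rows:
        raise ValidationError("no estimates to evaluate")
    df = pd.DataFrame(rows)

    def stats_table(keys: list[str]) -> pd.DataFrame:
        out = []
        if keys:
            grouped = df.groupby(keys, sort=True)
        else:
            grouped = [((), df)]
        for key, sub in grouped:
            if not isinstance(key, tuple):
                key = (key,)
            row = dict(zip(keys, key))
            row.update(
                _group_stats_row(
                    sub["ca_years"].to_numpy(), sub["da_years"].to_numpy()
                )
            )
            out.append(row)
        table = pd.DataFrame(out)
        for col in STRATIFIERS:
            if col not in table.columns:
                table.insert(list(STRATIFIERS).index(col), col, "all")
        return table[list(STRATIFIERS) + [c for c in table.columns if c not in STRATIFIERS]]

    stats_df = stats_table([s for s in STRATIFIERS if s in stratify_by])
    overall_df = stats_table(["method"] if "method" in stratify_by else [])

    sex_rows = []
    for method, sub in df.groupby("method", sort=True):
        errs_m = (sub.loc[sub.sex == "M", "ca_years"] - sub.loc[sub.sex == "M", "da_years"]).to_numpy()
        errs_f = (sub.loc[sub.sex == "F", "ca_years"] - sub.loc[sub.sex == "F", "da_years"]).to_numpy()
        if errs_m.size >= 2 and errs_f.size >= 2:
            res = independent_t_test(errs_m, errs_f)
            sex_rows.append(
                {
                    "method": method,
                    "n_male": errs_m.size,
                    "n_female": errs_f.size,
                    "me_male": float(errs_m.mean()),
                    "me_female": float(errs_f.mean()),
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.pvalue,
                }
            )
    sex_df = pd.DataFrame(
        sex_rows,
        columns=["method", "n_male", "n_female", "me_male", "me_female", "t", "df", "p"],
    )
    return EvaluationReport(
        stats=stats_df,
        overall=overall_df,
        sex_comparison=sex_df,
        stratify_by=tuple(stratify_by),
    )
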