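"""Reproducibility and method-comparison statistics.

Reproducibility of repeated measurements by multiple raters is
summarized with the intraclass correlation coefficient.  The model is
ICC(2,1): two-way random effects, absolute agreement, single measures —
raters are treated as a random sample of researchers, and absolute
values matter clinically.  From the two-way ANOVA mean squares
(MSR between subjects, MSC between raters, MSE residual) with n
subjects and k raters:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

The consistency variant ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE) is
available behind a flag.  The variance-component computation is
implemented here directly; only the standard distributional tests
(Shapiro-Wilk, paired t, Mann-Whitney U) are delegated to scipy.

Method comparison summarizes paired differences as mean +/- SD and
gates the test choice on normality of the differences (Shapiro-Wilk at
alpha = 0.05): paired t-test when normality is not rejected, otherwise
the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats as _sps

from .errors import StatisticsError

__all__ = ["ICCResult", "MethodComparison", "icc", "compare_methods"]

_NORMALITY_ALPHA = 0.05


@dataclass
class ICCResult:
    """Intraclass correlation with its ANOVA mean squares."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    model: str
    n: int
    k: int


def _as_matrix(study, parameter: Optional[str]) -> np.ndarray:
    if hasattr(study, "matrix"):
        if parameter is None:
            raise ValueError("parameter name required when passing a RaterStudy")
        return np.asarray(study.matrix(parameter), dtype=float)
    return np.asarray(study, dtype=float)


def icc(
    study,
    parameter: Optional[str] = None,
    model: str = "absolute",
) -> ICCResult:
    """ICC for an (n subjects) x (k raters) matrix of measurements.

    ``study`` may be a :class:`~dentoface.phantom.RaterStudy` (with
    ``parameter`` naming the column to extract) or a 2D array.
    ``model="absolute"`` gives ICC(2,1); ``model="consistency"`` gives
    ICC(3,1).  Raises :class:`StatisticsError` when the total variance
    is zero (the coefficient is undefined).
    """
    x = _as_matrix(study, parameter)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D matrix, got shape {x.shape}")
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatisticsError(
            f"ICC needs >= 2 subjects and >= 2 raters, got {n} x {k}"
        )
    if not np.all(np.isfinite(x)):
        raise StatisticsError("ICC input contains missing/non-finite cells")
    if np.ptp(x) == 0:
        raise StatisticsError("zero total variance: ICC undefined")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    # perfect agreement: identical rater columns with subject variance.
    # Returned as exactly 1 to avoid round-off in the mean-square ratio.
    if np.all(x == x[:, :1]):
        value = 1.0
    elif model == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise StatisticsError("zero denominator: ICC undefined")
        value = (msr - mse) / denom
    elif model == "consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise StatisticsError("zero denominator: ICC undefined")
        value = (msr - mse) / denom
    else:
        raise ValueError(f"model must be 'absolute' or 'consistency', got {model!r}")
    model_name = (
        "two_way_random_absolute_single" if model == "absolute"
        else "two_way_mixed_consistency_single"
    )
    return ICCResult(
        icc=float(value),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        model=model_name,
        n=n,
        k=k,
    )


@dataclass
class MethodComparison:
    """Paired difference summary between two measurement methods."""

    mean_diff: float
    sd_diff: float
    p_value: float
    test_used: Optional[str]  # "paired_t" | "mann_whitney" | None if degenerate
    normality_p: float
    n: int
    degenerate: bool = False


def compare_methods(a, b) -> MethodComparison:
    """Compare paired measurements from two methods.

    Differences ``a - b`` are summarized as mean +/- SD (ddof=1).
    Shapiro-Wilk on the differences gates the test: paired t when
    normality is not rejected at 0.05, Mann-Whitney U otherwise.
    Identical inputs are reported as degenerate (no test applies).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise StatisticsError(
            f"paired samples differ in length: {a.size} vs {b.size}"
        )
    if a.size < 3:
        raise StatisticsError(f"need >= 3 pairs, got {a.size}")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if sd_diff == 0.0:
        return MethodComparison(
            mean_diff=mean_diff,
            sd_diff=0.0,
            p_value=float("nan"),
            test_used=None,
            normality_p=float("nan"),
            n=a.size,
            degenerate=True,
        )
    normality_p = float(_sps.shapiro(diffs).pvalue)
    if normality_p >= _NORMALITY_ALPHA:
        test_used = "paired_t"
        p = float(_sps.ttest_rel(a, b).pvalue)
    else:
        test_used = "mann_whitney"
        p = float(_sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return MethodComparison(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        p_value=p,
        test_used=test_used,
        normality_p=normality_p,
        n=a.size,
    )
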