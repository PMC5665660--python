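"""Method-validation statistics: ICC, paired CV, manual-vs-auto regression.

These are the agreement measures used to validate an automated counter
against repeated runs and human observers: a two-way intraclass correlation
for repeatability/reproducibility, the coefficient of variation of paired
differences, and ordinary least squares with r^2 for accuracy against
manual counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RatingsMatrix:
    """n_subjects x n_raters measurements (e.g. LD counts per image from two
    observers). Rows with missing cells are dropped with a warning."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"ratings must be 2-D, got shape {v.shape}")
        keep = np.isfinite(v).all(axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} subject row(s) with missing cells")
            v = v[keep]
        if v.shape[0] < 2:
            raise ValueError("need >= 2 subjects with complete ratings")
        if v.shape[1] < 2:
            raise ValueError("need >= 2 raters")
        self.values = v


@dataclass
class PairedSeries:
    """Two equal-length vectors of paired measurements of the same images."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be equal-length 1-D vectors")
        if a.size < 2:
            raise ValueError("need >= 2 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("paired series must be finite")
        self.a, self.b = a, b


def _two_way_mean_squares(v: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way ANOVA on a subjects x raters table."""
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((v - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(m: RatingsMatrix, variant: str = "absolute_agreement") -> float:
    """Single-measurement two-way intraclass correlation.

    ``absolute_agreement`` is ICC(2,1) — raters as random effects, rater
    offsets count against agreement; ``consistency`` is ICC(3,1) — rater
    offsets forgiven. Both come from the mean squares of the two-way ANOVA:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    """
    v = m.values
    n, k = v.shape
    if np.allclose(v.mean(axis=1), v.mean(axis=1)[0]):
        warnings.warn("zero between-subject variance; ICC undefined, returning 0")
        return 0.0
    msr, msc, mse = _two_way_mean_squares(v)
    if variant == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return float((msr - mse) / denom)


def cv_paired(p: PairedSeries) -> float:
    """Coefficient of variation of paired differences, in percent.

    100 * sd(a - b) / mean(pooled a and b), with the sample SD (n-1). The
    pooled mean is the mean over both columns together.
    """
    pooled_mean = float(np.mean(np.concatenate([p.a, p.b])))
    if pooled_mean == 0:
        raise ValueError("pooled mean is zero; CV undefined")
    sd_diff = float(np.std(p.a - p.b, ddof=1))
    return 100.0 * sd_diff / pooled_mean


def linreg_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r^2).

    r^2 is the squared Pearson correlation. A constant y has no linear
    relation to explain: r^2 is defined as 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.ptp(y) == 0:
        warnings.warn("y is constant; r^2 defined as 0")
        res = stats.linregress(x, y)
        return float(res.slope), float(res.intercept), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
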