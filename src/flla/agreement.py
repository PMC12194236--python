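"""Method-comparison and reliability statistics.

Implements, from first principles, the battery used to validate a new
measurement method against a reference and against repeated ratings:

* two-way random-effects, absolute-agreement intraclass correlation for
  averaged measurements — ICC(2,k), the McGraw & Wong ICC(A,k) — with its
  95% confidence interval;
* Bland–Altman analysis (bias and limits of agreement);
* Pearson product-moment correlation with the t-transform p-value;
* simple linear regression with R² and the standard error of the estimate.

The ICC is built on the standard two-way ANOVA decomposition without
replication: for an n-subjects × k-measurements complete matrix,

    MSR = between-subjects mean square        (df n−1)
    MSC = between-measurements mean square    (df k−1)
    MSE = residual mean square                (df (n−1)(k−1))

    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

Under absolute agreement a systematic offset between raters (MSC > 0)
lowers the coefficient, unlike consistency-type ICCs.  The confidence
interval follows McGraw & Wong's ICC(A,1) procedure (F-quantiles with a
Satterthwaite-approximated denominator df) stepped up to k measurements by
the Spearman–Brown relation — the same procedure the psych R package uses.

Interpretation bands follow Koo & Li (2016): <0.5 poor, 0.5–0.75 moderate,
0.75–0.9 good, >0.9 excellent (boundary values fall in the lower band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "BlandAltmanResult",
    "RegressionResult",
    "anova_mean_squares",
    "icc2k",
    "bland_altman",
    "loa_t_multiplier",
    "pearson_r",
    "ols_fit",
    "interpret_icc",
]

# Total-variance floor below which a ratings matrix is treated as constant
# (degrees²; far below any credible between-subject angle variance).
_CONSTANT_TOL = 1e-12


@dataclass(frozen=True)
class RatingsMatrix:
    """A complete n_subjects × k_measurements grid of angle values (degrees).

    ``measurement_labels`` name the columns (raters, readings or sessions,
    depending on the reliability design).  Incomplete rows must be rejected
    upstream; missing cells are a hard error here.
    """

    values: np.ndarray
    subject_ids: tuple = ()
    measurement_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"ratings must be 2-D (subjects × measurements), got ndim={arr.ndim}")
        n, k = arr.shape
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if k < 2:
            raise ValueError(f"need at least 2 measurements per subject, got {k}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ratings matrix contains missing or non-finite cells")
        object.__setattr__(self, "values", arr)
        if self.subject_ids and len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")
        if self.measurement_labels and len(self.measurement_labels) != k:
            raise ValueError("measurement_labels length does not match number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,k) estimate with confidence interval and ANOVA components."""

    estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    interpretation: str = field(default="")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError(
                f"inconsistent ICC interval: {self.ci_low} <= {self.estimate} <= {self.ci_high}"
            )
        if not self.interpretation:
            object.__setattr__(self, "interpretation", interpret_icc(self.estimate))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement for paired differences (method1 − method2)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression y = intercept + slope·x with fit diagnostics."""

    intercept: float
    slope: float
    r2: float
    see: float
    r: float
    p_value: float
    n: int


def anova_mean_squares(m: RatingsMatrix) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=measurements).

    Returns ``(ms_rows, ms_cols, ms_error)``; the underlying sums of squares
    satisfy SSR + SSC + SSE = total sum of squares about the grand mean.
    """
    v = m.values
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((v - grand) ** 2))
    sse = sst - ssr - ssc
    # tiny negative residual from cancellation is numerically zero
    if sse < 0:
        if sse < -1e-8 * max(sst, 1.0):
            raise AssertionError(f"negative residual sum of squares: {sse}")
        sse = 0.0
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc2k(m: RatingsMatrix, confidence: float = 0.95) -> ICCResult:
    """Absolute-agreement two-way random-effects ICC for the mean of k ratings.

    Raises ``ValueError`` for a constant matrix (the coefficient is undefined
    when there is no variance to apportion).
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    v = m.values
    n, k = v.shape
    if float(np.sum((v - v.mean()) ** 2)) <= _CONSTANT_TOL:
        raise ValueError("ICC undefined: ratings matrix is constant (zero total variance)")
    msr, msc, mse = anova_mean_squares(m)

    denom = msr + (msc - mse) / n
    if denom <= 0:
        # only possible when the residual mean square swamps the subject
        # variance (a negative variance-component estimate): the
        # absolute-agreement coefficient is degenerate, not just low
        raise ValueError(
            "ICC undefined: residual variance exceeds subject variance "
            f"(MSR={msr:.4g}, MSC={msc:.4g}, MSE={mse:.4g})"
        )
    est = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1), then Spearman-Brown step-up to k.
    alpha = 1.0 - confidence
    r1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse <= _CONSTANT_TOL * max(msr, 1.0) and msc <= _CONSTANT_TOL * max(msr, 1.0):
        # perfect agreement: interval degenerates
        lo1 = hi1 = 1.0
    else:
        a = k * r1 / (n * (1.0 - r1)) if r1 < 1.0 else math.inf
        b = 1.0 + k * r1 * (n - 1.0) / (n * (1.0 - r1)) if r1 < 1.0 else math.inf
        if math.isinf(a):
            lo1 = hi1 = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
            vdf = num / den if den > 0 else (n - 1.0) * (k - 1.0)
            if not math.isfinite(vdf) or vdf <= 0:
                # Satterthwaite approximation breaks down for negative
                # estimates; fall back to the residual df
                vdf = (n - 1.0) * (k - 1.0)
            f_star = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, vdf)
            f_star2 = stats.f.ppf(1.0 - alpha / 2.0, vdf, n - 1.0)
            common = k * msc + (k * n - k - n) * mse
            with np.errstate(all="ignore"):  # non-finite bounds handled below
                lo1 = n * (msr - f_star * mse) / (f_star * common + n * msr)
                hi1 = n * (f_star2 * msr - mse) / (common + n * f_star2 * msr)
            if not math.isfinite(lo1):
                lo1 = -1.0
            if not math.isfinite(hi1):
                hi1 = 1.0
            lo1 = min(max(lo1, -1.0), 1.0)
            hi1 = min(max(hi1, lo1), 1.0)

    def _step_up(r: float) -> float:
        # Spearman-Brown; below r = -1/(k-1) the step-up diverges, which only
        # happens for pathological negative bounds — pin those to -1
        denom = 1.0 + (k - 1.0) * r
        if denom <= 0:
            return -1.0
        return k * r / denom

    lo, hi = _step_up(lo1), _step_up(hi1)
    lo = min(lo, est)
    hi = max(hi, est)
    return ICCResult(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        confidence=confidence,
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n=n,
        k=k,
    )


def loa_t_multiplier(n: int, confidence: float = 0.95) -> float:
    """t-quantile alternative to the normal 1.96 limits-of-agreement multiplier."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    return float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))


def bland_altman(
    x: Sequence[float], y: Sequence[float], multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of paired measurements.

    Differences are taken as ``x − y`` (the caller fixes orientation); the
    limits of agreement are bias ± multiplier·SD with the sample (n−1)
    standard deviation.  Pass :func:`loa_t_multiplier` output for small-sample
    t-based limits.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError(f"paired inputs must be equal-length 1-D vectors, got {xa.shape} vs {ya.shape}")
    n = xa.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("paired inputs contain non-finite values")
    d = xa - ya
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        multiplier=multiplier,
        n=n,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value.

    The p-value uses the exact null transform t = r·√((n−2)/(1−r²)) with
    n−2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx <= 0 or syy <= 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares line y = a + b·x with R², SEE, r and p.

    SEE (standard error of the estimate) is √(SSE/(n−2)), the residual
    standard deviation in the response units.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    dx = xa - xa.mean()
    sxx = float(dx @ dx)
    if sxx <= 0:
        raise ValueError("regression undefined: constant predictor")
    dy = ya - ya.mean()
    slope = float(dx @ dy) / sxx
    intercept = float(ya.mean() - slope * xa.mean())
    resid = ya - (intercept + slope * xa)
    sse = float(resid @ resid)
    sst = float(dy @ dy)
    if sst <= 0:
        # constant response: the fitted line is flat and explains nothing
        r2 = 0.0
        r, p = 0.0, 1.0
    else:
        r2 = 1.0 - sse / sst
        r, p = pearson_r(xa, ya)
    see = math.sqrt(sse / (n - 2))
    return RegressionResult(
        intercept=intercept, slope=slope, r2=r2, see=see, r=r, p_value=p, n=n
    )


def interpret_icc(estimate: float) -> str:
    """Koo & Li qualitative band for an ICC estimate."""
    if estimate > 1.0 + 1e-12:
        raise ValueError(f"ICC estimate cannot exceed 1, got {estimate}")
    if estimate > 0.9:
        return "excellent"
    if estimate > 0.75:
        return "good"
    if estimate >= 0.5:
        return "moderate"
    return "poor"
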