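"""Method-comparison and reliability statistics.

Agreement between two STV measurements (manual vs semiautomated, or repeat
readings) is quantified the standard way: Bland–Altman differences with a
t-based 95% CI of the mean difference and 1.96·SD limits of agreement
(LoA), two-way mixed-effects consistency ICC(3,1) with an F-based CI, and
ordinary least squares of one method on the other where a slope near 1
indicates agreement.  ``loa_from_summary`` bridges a published (mean
difference, 95% CI, n) summary back to the LoA it implies: the CI uses the
exact t quantile, the LoA the conventional 1.96 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired values (mm^3) from two methods or ratings."""

    a: np.ndarray
    b: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("a and b must be 1-D arrays of equal length")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        if self.ids is not None and len(self.ids) != a.size:
            raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    ci95_mean: tuple[float, float]
    loa95: tuple[float, float]
    log_transformed: bool = False


def bland_altman(pairs: PairedMeasurements,
                 log_transform: bool = False) -> BlandAltmanResult:
    """Bland–Altman analysis of the differences a − b.

    SD uses the n−1 denominator; the CI of the mean difference is
    mean ± t(0.975, n−1)·SD/√n; the limits of agreement are mean ± 1.96·SD.
    With ``log_transform`` the analysis runs on natural logs (all values
    must be positive).
    """
    a, b = pairs.a, pairs.b
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        a, b = np.log(a), np.log(b)
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    half = t * sd / np.sqrt(n)
    return BlandAltmanResult(
        n=n, mean_diff=mean, sd_diff=sd,
        ci95_mean=(mean - half, mean + half),
        loa95=(mean - 1.96 * sd, mean + 1.96 * sd),
        log_transformed=log_transform)


def loa_from_summary(mean_diff: float, ci_low: float, ci_high: float,
                     n: int) -> tuple[float, float]:
    """Recover 1.96·SD limits of agreement from a printed summary.

    From a reported mean difference with its t-based 95% CI at sample size
    ``n``: SD = CI half-width · √n / t(0.975, n−1), LoA = mean ± 1.96·SD.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not ci_low < mean_diff < ci_high:
        raise ValueError(
            f"inconsistent interval: need ci_low < mean_diff < ci_high, got "
            f"({ci_low}, {mean_diff}, {ci_high})")
    half = (ci_high - ci_low) / 2.0
    t = float(stats.t.ppf(0.975, n - 1))
    sd = half * np.sqrt(n) / t
    return (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)


def icc_3_1(ratings: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, tuple[float, float]]:
    """Two-way mixed-effects, single-measure, consistency ICC(3,1).

    ``ratings`` is an n targets × k raters table with no missing cells.
    ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS) from the two-way ANOVA mean
    squares; the 95% CI is the standard F-distribution interval
    (Shrout & Fleiss convention).
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D table (targets x raters)")
    if np.isnan(x).any():
        raise ValueError("ratings table has missing cells")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 targets and 2 raters")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms + (k - 1) * ems == 0:
        return 1.0, (1.0, 1.0)
    icc = (bms - ems) / (bms + (k - 1) * ems)

    if ems == 0:
        return float(icc), (float(icc), float(icc))
    f_obs = bms / ems
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(0.975, df1, df2)
    f_u = f_obs * stats.f.ppf(0.975, df2, df1)
    lower = (f_l - 1) / (f_l + k - 1)
    upper = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lower), float(upper))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def agreement_regression(pairs: PairedMeasurements) -> RegressionResult:
    """OLS of method b on method a; slope near 1 indicates agreement."""
    if pairs.n < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.var(pairs.a) == 0:
        raise ValueError("method a has zero variance; slope undefined")
    res = stats.linregress(pairs.a, pairs.b)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2))
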