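"""Cell-shape metrics and the statistics used throughout the analysis.

Shape complexity is summarized as *lobeyness*, the ratio of a cell's
perimeter to the perimeter of its convex hull: exactly 1 for convex
outlines, growing as lobes and necks develop, and invariant to
rotation, translation and uniform scaling.  The rate of shape
formation is read off an ordinary least-squares regression of
lobeyness on cell area across a developmental time course; group
comparisons use Welch's unpaired two-tailed t-test with means +/- 95%
confidence intervals, the convention used for every comparison here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .contour import CellContour

__all__ = [
    "ShapeMetrics",
    "WelchResult",
    "RegressionResult",
    "shape_metrics",
    "shape_rate_regression",
    "compare_slopes",
    "welch_t_test",
    "mean_ci",
]


@dataclass
class ShapeMetrics:
    area_um2: float
    perimeter_um: float
    hull_perimeter_um: float
    lobeyness: float


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean1: float
    mean2: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    slope_se: float
    n: int


def shape_metrics(contour: CellContour) -> ShapeMetrics:
    """Area, perimeter, convex-hull perimeter and lobeyness of a cell.

    Area comes from the shoelace formula scaled by the squared pixel
    size; lobeyness = perimeter / convex-hull perimeter (>= 1, with
    equality exactly for convex outlines).
    """
    poly = contour.polygon  # CellContour guarantees a simple polygon
    um_per_px = contour.pixel_size_nm / 1000.0
    perim = poly.length * um_per_px
    hull_perim = poly.convex_hull.length * um_per_px
    return ShapeMetrics(
        area_um2=poly.area * um_per_px**2,
        perimeter_um=perim,
        hull_perimeter_um=hull_perim,
        lobeyness=perim / hull_perim,
    )


def shape_rate_regression(area: np.ndarray, lobeyness: np.ndarray) -> RegressionResult:
    """OLS regression of lobeyness on cell area.

    The slope is the rate of shape formation per unit areal growth;
    its 95% CI uses the t distribution with n - 2 df.  Cells are
    pooled across individuals.
    """
    import statsmodels.api as sm

    x = np.asarray(area, dtype=float)
    y = np.asarray(lobeyness, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs at least 3 points")
    if x.std() == 0:
        raise ValueError("zero variance in area")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        slope_se=float(model.bse[1]),
        n=len(x),
    )


def compare_slopes(r1: RegressionResult, r2: RegressionResult) -> tuple[float, float]:
    """Welch-style t test of two independent regression slopes.

    t = (b1 - b2) / sqrt(se1^2 + se2^2) with Welch-Satterthwaite df on
    the slope standard errors; returns (t, two-tailed p).
    """
    se2 = r1.slope_se**2 + r2.slope_se**2
    t = (r1.slope - r2.slope) / np.sqrt(se2)
    df = se2**2 / (
        r1.slope_se**4 / max(r1.n - 2, 1) + r2.slope_se**4 / max(r2.n - 2, 1)
    )
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def mean_ci(sample: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-quantile confidence interval (mean, lo, hi)."""
    x = np.asarray(sample, dtype=float)
    m = float(x.mean())
    if len(x) < 2:
        return m, m, m
    sem = x.std(ddof=1) / np.sqrt(len(x))
    h = float(sps.t.ppf(0.5 + confidence / 2, len(x) - 1) * sem)
    return m, m - h, m + h


def welch_t_test(sample1: np.ndarray, sample2: np.ndarray) -> WelchResult:
    """Welch's unpaired two-tailed t-test (unequal variances).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), df by Welch-Satterthwaite,
    p two-tailed from the t distribution; group means are reported with
    95% CIs.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    m1, lo1, hi1 = mean_ci(a)
    m2, lo2, hi2 = mean_ci(b)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean1=m1,
        mean2=m2,
        ci1=(lo1, hi1),
        ci2=(lo2, hi2),
    )
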