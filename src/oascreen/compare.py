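"""Method cross-validation: recovery, linearity, Passing-Bablok, testing.

Passing-Bablok regression is the field's standard symmetric,
non-parametric method-comparison fit: the slope is the shifted median of
all pairwise slopes (offset by the count of slopes below -1, with slopes
equal to -1 excluded), which makes the estimate invariant to exchanging
the two methods up to inversion and robust to outliers. Confidence bounds
come from the rank-based normal approximation. A slope confidence interval
containing 1 and an intercept interval containing 0 indicate the methods
agree.

Recovery of spiked analytes is assessed by regressing the measured result
on the weighed-in amount (recovery % = 100 x slope); the clinical
acceptance band is 80-120%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PBResult",
    "AnalyteComparison",
    "CompareError",
    "passing_bablok",
    "assess_recovery_linearity",
    "recovery_ratio",
    "significance_test",
    "compare_methods",
]

RECOVERY_BAND = (80.0, 120.0)
SLOPE_BAND = (0.8, 1.2)


class CompareError(ValueError):
    """Raised for designs too small or degenerate to compare."""


@dataclass
class PBResult:
    """Passing-Bablok fit with 95% confidence bounds."""

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    intercept_ci_low: float
    intercept_ci_high: float
    n: int


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    valid = dx != 0
    slopes = dy[valid] / dx[valid]
    # the original estimator discards slopes of exactly -1 (they carry no
    # direction information under exchange of the two methods)
    return slopes[slopes != -1.0]


def passing_bablok(x, y, alpha: float = 0.05) -> PBResult:
    """Classic Passing-Bablok regression of method y on method x.

    Slope = shifted median of the pairwise slopes (y_j - y_i)/(x_j - x_i),
    offset by K = #{slopes < -1}; intercept = median(y - slope*x). The
    confidence interval uses the rank normal approximation with variance
    n(n-1)(2n+5)/18.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise CompareError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise CompareError("need >= 3 paired observations")
    if np.allclose(x, x[0]):
        raise CompareError("all x identical: slope undefined")
    slopes = np.sort(_pairwise_slopes(x, y))
    N = len(slopes)
    if N < 1:
        raise CompareError("no valid pairwise slopes")
    K = int(np.sum(slopes < -1.0))

    if N % 2 == 1:
        b = slopes[(N - 1) // 2 + K]
    else:
        b = 0.5 * (slopes[N // 2 - 1 + K] + slopes[N // 2 + K])

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    w = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - w) / 2.0))
    m2 = N - m1 + 1
    lo_idx = min(max(m1 + K - 1, 0), N - 1)
    hi_idx = min(max(m2 + K - 1, 0), N - 1)
    b_lo, b_hi = float(slopes[lo_idx]), float(slopes[hi_idx])

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return PBResult(
        slope=float(b),
        intercept=a,
        slope_ci_low=b_lo,
        slope_ci_high=b_hi,
        intercept_ci_low=a_lo,
        intercept_ci_high=a_hi,
        n=n,
    )


def assess_recovery_linearity(spiked, measured) -> tuple[float, float, float]:
    """Recovery and linearity from spiked amounts vs measured results.

    Regresses measured on weighed-in amount (>= 3 levels); returns
    (recovery %, slope, r2) with recovery % = 100 x slope.
    """
    spiked = np.asarray(spiked, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if len(spiked) < 3:
        raise CompareError("need >= 3 spiked levels")
    if np.allclose(spiked, spiked[0]):
        raise CompareError("all spiked amounts identical")
    fit = stats.linregress(spiked, measured)
    return 100.0 * float(fit.slope), float(fit.slope), float(fit.rvalue**2)


def recovery_ratio(spiked, measured) -> float:
    """Simple ratio recovery %: mean of measured/spiked over positive spikes."""
    spiked = np.asarray(spiked, dtype=float)
    measured = np.asarray(measured, dtype=float)
    mask = spiked > 0
    if not mask.any():
        raise CompareError("no positive spiked amounts")
    return float(100.0 * np.mean(measured[mask] / spiked[mask]))


def significance_test(a, b, alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided difference test: Welch t when both groups look normal.

    Normality is screened per group with Shapiro-Wilk at the same alpha;
    if either group departs (or is degenerate), the Mann-Whitney U test is
    used instead. Returns (p_value, 't' | 'mann_whitney').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise CompareError("each group needs n >= 3")

    def _normal(v: np.ndarray) -> bool:
        if np.allclose(v, v[0]):
            return False
        return stats.shapiro(v).pvalue > alpha

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue), "t"
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
        return 1.0, "mann_whitney"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "mann_whitney"


@dataclass
class AnalyteComparison:
    """Full method-comparison summary for one analyte."""

    analyte: str
    recovery_pct: float
    recovery_acceptable: bool
    linearity_slope: float
    linearity_r2: float
    pb: PBResult
    p_value: float
    test_used: str
    slope_in_range: bool


def compare_methods(
    analyte: str,
    conc_test,
    conc_ref,
    spiked=None,
) -> AnalyteComparison:
    """Recovery/linearity, Passing-Bablok and significance for one analyte.

    ``spiked`` (weighed-in amounts) enables the recovery regression; when
    absent, recovery is computed against the reference method's values.
    """
    conc_test = np.asarray(conc_test, dtype=float)
    conc_ref = np.asarray(conc_ref, dtype=float)
    basis = np.asarray(spiked, dtype=float) if spiked is not None else conc_ref
    recovery, slope, r2 = assess_recovery_linearity(basis, conc_test)
    pb = passing_bablok(conc_ref, conc_test)
    p, test_used = significance_test(conc_test, conc_ref)
    return AnalyteComparison(
        analyte=analyte,
        recovery_pct=recovery,
        recovery_acceptable=RECOVERY_BAND[0] <= recovery <= RECOVERY_BAND[1],
        linearity_slope=slope,
        linearity_r2=r2,
        pb=pb,
        p_value=p,
        test_used=test_used,
        slope_in_range=SLOPE_BAND[0] <= pb.slope <= SLOPE_BAND[1],
    )
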