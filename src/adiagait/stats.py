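"""Statistical layer: paired comparisons, zero-intercept fits, ANCOVA, DTW.

Paired condition comparisons are gated on a Shapiro-Wilk normality test of
the differences (paired t when normal, Wilcoxon signed rank otherwise).
The linear law between normalized mean kinetic energy and normalized cycle
frequency is fitted by least squares through the origin, with a
t-distribution confidence interval on the slope; the between-condition
comparison of slopes is a zero-intercept ANCOVA with a condition
interaction term. Dynamic time warping (on z-normalized traces) quantifies
the distance between phase-space trajectories across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .signals import UniformSignal


@dataclass(frozen=True)
class PairedComparison:
    test: str            # "paired-t" or "wilcoxon"
    statistic: float
    p_value: float
    normality_p: float   # Shapiro-Wilk p on the differences
    n: int

    def summary_row(self, x: np.ndarray, y: np.ndarray) -> dict:
        """Reporting convention: mean +/- SD for the t branch, median [q1-q3]
        for the Wilcoxon branch."""
        def fmt(v: np.ndarray) -> str:
            if self.test == "paired-t":
                return f"{np.mean(v):.4g} ± {np.std(v, ddof=1):.4g}"
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            return f"{med:.4g} [{q1:.4g}–{q3:.4g}]"
        return {"A": fmt(np.asarray(x)), "B": fmt(np.asarray(y)),
                "test": self.test, "p": self.p_value}


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int
    interaction: float | None = None    # slope difference (ANCOVA only)
    interaction_p: float | None = None


def paired_compare(x, y, alpha: float = 0.05) -> PairedComparison:
    """Shapiro-gated paired comparison of two matched samples.

    Paired t-test when the differences pass Shapiro-Wilk at ``alpha``,
    Wilcoxon signed rank otherwise (zero differences dropped; exact null
    distribution for n <= 25, normal approximation above).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("paired comparison needs equal lengths >= 3")
    d = x - y
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    sh_stat, sh_p = sps.shapiro(d)
    if sh_p >= alpha:
        stat, p = sps.ttest_rel(x, y)
        return PairedComparison("paired-t", float(stat), float(p), float(sh_p), x.size)
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 else "approx"
    stat, p = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                           method=method)
    return PairedComparison("wilcoxon", float(stat), float(p), float(sh_p), x.size)


def slope_fit(x, y, conf: float = 0.95) -> SlopeFit:
    """Least squares through the origin: k = sum(xy)/sum(x^2).

    The slope CI uses the t distribution with n-1 degrees of freedom;
    R^2 is computed against the zero-intercept null (SS_tot = sum y^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("slope fit needs equal lengths >= 3")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise DegenerateDataError("all x values are zero")
    k = float(np.sum(x * y) / sxx)
    resid = y - k * x
    n = x.size
    s2 = float(np.sum(resid**2) / (n - 1))
    se = np.sqrt(s2 / sxx)
    tcrit = sps.t.ppf(0.5 + conf / 2.0, n - 1)
    syy = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else float("nan")
    return SlopeFit(k, k - tcrit * se, k + tcrit * se, r2, n)


def ancova_zero_intercept(pairs_a, pairs_b) -> SlopeFit:
    """Compare zero-intercept linear trends of two groups.

    Fits y = k x + k_delta (x * 1[group B]) with no intercept; ``slope``
    is the group-A slope k, ``interaction`` the slope difference k_delta
    with its t-test p-value.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in pairs_a)
    xb, yb = (np.asarray(v, dtype=float) for v in pairs_b)
    if xa.size < 3 or xb.size < 3:
        raise InsufficientDataError("each group needs n >= 3")
    if np.all(xa == 0) or np.all(xb == 0):
        raise DegenerateDataError("a group has all x = 0")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    grp = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    design = np.column_stack([x, x * grp])
    fit = sm.OLS(y, design).fit()
    k, k_delta = (float(v) for v in fit.params)
    se_delta = float(fit.bse[1])
    exact_fit = fit.ssr <= 1e-20 * float(np.sum(y * y))
    if exact_fit or se_delta == 0.0 or not np.isfinite(se_delta):
        # residuals at rounding level: the t ratio is noise, not evidence
        p_delta = 1.0 if abs(k_delta) <= 1e-8 * max(1.0, abs(k)) else 0.0
    else:
        p_delta = float(fit.pvalues[1])
    ci = fit.conf_int()
    return SlopeFit(
        slope=k,
        ci_low=float(ci[0][0]),
        ci_high=float(ci[0][1]),
        r_squared=float(fit.rsquared) if np.isfinite(fit.rsquared) else 1.0,
        n=x.size,
        interaction=k_delta,
        interaction_p=p_delta,
    )


def _z_normalize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0.0:
        raise DegenerateDataError("z-normalization undefined for constant input")
    return (v - v.mean()) / sd


def dtw_distance(a, b, band_fraction: float | None = None) -> float:
    """Dynamic time warping distance between two z-normalized traces.

    Classic symmetric step pattern (diagonal/horizontal/vertical moves,
    unit weights) with absolute-difference local cost; inputs are
    z-normalized first so the distance is invariant to affine transforms.
    ``band_fraction`` enables a Sakoe-Chiba band of that fraction of the
    longer series (for long inputs).
    """
    va = a.values if isinstance(a, UniformSignal) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, UniformSignal) else np.asarray(b, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise InsufficientDataError("DTW needs series of length >= 2")
    va = _z_normalize(va)
    vb = _z_normalize(vb)
    n, m = va.size, vb.size
    band = None
    if band_fraction is not None:
        if not 0.0 < band_fraction <= 1.0:
            raise ParameterError("band_fraction must lie in (0, 1]")
        band = max(int(band_fraction * max(n, m)), abs(n - m) + 1)
    inf = float("inf")
    prev = [inf] * (m + 1)
    prev[0] = 0.0
    la = va.tolist()
    lb = vb.tolist()
    for i in range(1, n + 1):
        cur = [inf] * (m + 1)
        ai = la[i - 1]
        j_lo, j_hi = 1, m
        if band is not None:
            j_lo = max(1, i - band)
            j_hi = min(m, i + band)
        for j in range(j_lo, j_hi + 1):
            cost = abs(ai - lb[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = cost + best
        prev = cur
    return float(prev[m])
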