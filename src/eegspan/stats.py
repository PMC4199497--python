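"""Group statistics: Welch t-tests, Holm correction and robust
regression of network metrics against CRS-R scores.

Families for the multiple-comparison correction follow the analysis
design: within each metric, p-values are corrected across the frequency
bands tested (never across metrics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "RegressionResult",
    "welch_ttest",
    "holm_correct",
    "robust_regression",
]


@dataclass
class StatResult:
    t: float
    df: float          # Welch–Satterthwaite, real-valued
    p: float
    p_corrected: float | None = None
    metric: str = ""
    band: str = ""
    mean_a: float = float("nan")
    mean_b: float = float("nan")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    slope_se: float
    predictor: str = ""
    response: str = ""
    subset: str = "all"
    n: int = 0

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = _st.norm.ppf(0.5 + level / 2.0)
        return (self.slope - z * self.slope_se, self.slope + z * self.slope_se)


def welch_ttest(values_a, values_b, metric: str = "", band: str = "") -> StatResult:
    """Unpaired two-sided t-test assuming unequal variances."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        df = float(len(a) + len(b) - 2)
    else:
        res = _st.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return StatResult(t=t, df=df, p=p, metric=metric, band=band,
                      mean_a=float(a.mean()), mean_b=float(b.mean()))


def holm_correct(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def robust_regression(x, y, predictor: str = "", response: str = "",
                      subset: str = "all") -> RegressionResult:
    """Robust linear fit of ``y`` on ``x`` (IRLS, Tukey bisquare).

    R² is the squared Pearson correlation between fitted and observed
    responses; the slope p-value comes from the robust standard error
    (normal approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("robust regression needs at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor; slope undefined")
    design = sm.add_constant(x)
    fit = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight()).fit()
    intercept, slope = fit.params
    se = float(fit.bse[1])
    z = slope / se if se > 0 else np.inf
    p = float(2 * _st.norm.sf(abs(z)))
    fitted = fit.fittedvalues
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r_squared=r2, p_slope=p, slope_se=se,
                            predictor=predictor, response=response,
                            subset=subset, n=len(x))
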