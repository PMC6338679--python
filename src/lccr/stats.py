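"""Lifespan-trajectory inference: trajectory fits, U-shape and group tests.

The module bundles every statistic the contrast-ratio analysis needs:

* linear/quadratic OLS trajectory fits with a fixed-convention AIC,
* a two-lines (interrupted regression) test of U-shaped relationships,
* frequentist group comparisons (Student, Welch, paired t; variance F),
* the default Bayesian two-sample t-test (JZS Bayes factor with a Cauchy
  prior on the standardized effect), with Cohen's d and its CI,
* collinearity (VIF) and simple-association diagnostics.

OLS fitting is delegated to statsmodels; the JZS integrand, the two-lines
breakpoint search, and the AIC convention are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats

__all__ = [
    "ModelFit",
    "TwoLinesResult",
    "BayesTResult",
    "fit_polynomial",
    "compare_aic",
    "two_lines_test",
    "jzs_bayes_factor",
    "cohens_d_from_t",
    "student_t",
    "welch_t",
    "variance_ratio_test",
    "vif",
    "association",
    "paired_t",
]

DEFAULT_CAUCHY_SCALE = math.sqrt(2) / 2


@dataclass
class ModelFit:
    """An OLS fit with the quantities the trajectory analysis reports.

    ``aic = 2k - 2 log L`` where k counts every estimated parameter —
    intercept, slopes, and the residual variance — and log L is the full
    Gaussian maximum log-likelihood (2π constants included). Only AIC
    differences between models on the same response are meaningful, and
    those are invariant to the convention.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    df_resid: float
    resid_var: float
    r2: float
    adj_r2: float
    log_likelihood: float
    aic: float
    f_pvalue: float
    design: str
    response_checksum: float
    degenerate: bool = False


def _fit_ols(X: pd.DataFrame, y: np.ndarray, design: str) -> ModelFit:
    Xm = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xm.to_numpy())
    if rank < Xm.shape[1]:
        # name which added column kills the rank
        culprits = []
        cols = list(Xm.columns)
        for j in range(1, len(cols)):
            sub = Xm.iloc[:, : j + 1].to_numpy()
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                culprits.append(cols[j])
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    res = sm.OLS(y, Xm).fit()
    k = Xm.shape[1] + 1  # + residual variance
    rss = float(res.ssr)
    degenerate = rss <= 1e-12 * max(1.0, float(np.sum(y ** 2)))
    return ModelFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        resid_var=rss / res.nobs,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        log_likelihood=float(res.llf),
        aic=2 * k - 2 * float(res.llf),
        f_pvalue=float(res.f_pvalue) if res.df_model > 0 else float("nan"),
        design=design,
        response_checksum=float(np.sum(y) + np.sum(y ** 2)),
        degenerate=degenerate,
    )


def fit_polynomial(
    x,
    y,
    degree: int = 2,
    covariates: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
) -> ModelFit:
    """OLS fit of y on a degree-1 or degree-2 polynomial in x.

    ``covariates`` and ``interactions`` add extra design columns (e.g. sex,
    reference signal, TR indicator, age×sex). An exact fit is flagged
    ``degenerate`` rather than rejected.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in x or y")
    X = pd.DataFrame({"x": x})
    if degree == 2:
        X["x2"] = x ** 2
    parts = [X]
    for extra in (covariates, interactions):
        if extra is not None:
            parts.append(extra.reset_index(drop=True))
    X = pd.concat(parts, axis=1)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > k + 1, got n={len(y)} for k={X.shape[1]}")
    return _fit_ols(X, y, design=f"poly{degree}+{X.shape[1] - degree}cov")


def compare_aic(fit_a: ModelFit, fit_b: ModelFit) -> tuple[str, float]:
    """Winner ('a', 'b' or 'tie') and |AIC difference| for two fits.

    Both fits must describe the same response (checked via n and a response
    checksum); lower AIC wins.
    """
    if fit_a.n != fit_b.n:
        raise ValueError(f"fits have different n: {fit_a.n} vs {fit_b.n}")
    if not np.isclose(fit_a.response_checksum, fit_b.response_checksum, rtol=1e-10):
        raise ValueError("fits appear to describe different response vectors")
    diff = abs(fit_a.aic - fit_b.aic)
    if diff < 1e-12:
        return "tie", 0.0
    return ("a" if fit_a.aic < fit_b.aic else "b"), diff


@dataclass
class TwoLinesResult:
    """Interrupted-regression test of a U (or inverted-U) shape.

    The verdict is ``u_shape_confirmed`` only when both segment slopes are
    individually significant at α = 0.05 with opposite signs — the
    conservative both-slopes rule. Same-sign significant slopes give
    ``monotonic``; anything else is ``inconclusive``.
    """

    breakpoint_x: float
    slope_low: float
    z_low: float
    p_low: float
    slope_high: float
    z_high: float
    p_high: float
    n_low: int
    n_high: int
    verdict: str
    note: str = ""


def _interrupted_fit(x: np.ndarray, y: np.ndarray, c: float):
    low = x <= c
    n_low, n_high = int(low.sum()), int((~low).sum())
    X = np.column_stack([
        low.astype(float), x * low,
        (~low).astype(float), x * (~low),
    ])
    res = sm.OLS(y, X).fit()
    return res, n_low, n_high


def two_lines_test(x, y, breakpoint: float | None = None, alpha: float = 0.05) -> TwoLinesResult:
    """Two-lines test: separate regressions either side of a breakpoint.

    Without a supplied breakpoint the procedure (1) fits a quadratic and
    locates its vertex with a delta-method standard error, (2) applies a
    single "Robin Hood" reallocation step: the breakpoint moves within one
    vertex SE toward the stronger arm, handing observations to the weaker
    arm in proportion to the imbalance of the two slope |z|-scores, then
    (3) jointly fits the two unconstrained segments via a dummy-interaction
    design. The single adaptive step keeps the plateau false-positive rate
    near the nominal level, where a best-of-many candidate search does not.
    A vertex outside the observed x-range short-circuits to a ``monotonic``
    verdict based on a single-line fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("two-lines test needs n >= 10")

    note = ""
    if breakpoint is None:
        quad = fit_polynomial(x, y, degree=2)
        b1, b2 = quad.params["x"], quad.params["x2"]
        if abs(b2) < 1e-300:
            breakpoint_x = float(np.median(x))
            note = "quadratic term ~0; breakpoint at median x"
        else:
            vertex = -b1 / (2 * b2)
            n_low_at_vertex = int((x <= vertex).sum())
            if (not (x.min() <= vertex <= x.max())
                    or n_low_at_vertex < 3 or n - n_low_at_vertex < 3):
                lin = fit_polynomial(x, y, degree=1)
                slope = float(lin.params["x"])
                z = slope / float(lin.bse["x"])
                p = float(lin.pvalues["x"])
                return TwoLinesResult(
                    breakpoint_x=float(vertex), slope_low=slope, z_low=z, p_low=p,
                    slope_high=slope, z_high=z, p_high=p, n_low=n, n_high=0,
                    verdict="monotonic",
                    note="quadratic vertex outside (or at the edge of) the "
                         "observed x-range",
                )
            # delta-method SE of the vertex -b1/(2 b2)
            Xq = sm.add_constant(np.column_stack([x, x ** 2]))
            cov = sm.OLS(y, Xq).fit().cov_params()
            grad = np.array([0.0, -1 / (2 * b2), b1 / (2 * b2 ** 2)])
            var = float(grad @ np.asarray(cov) @ grad)
            se = math.sqrt(max(var, 0.0))
            res0, _, _ = _interrupted_fit(x, y, vertex)
            z_lo0 = abs(res0.params[1] / res0.bse[1])
            z_hi0 = abs(res0.params[3] / res0.bse[3])
            denom = z_lo0 + z_hi0
            c = vertex if denom == 0 else vertex + se * (z_lo0 - z_hi0) / denom
            c = float(min(max(c, x.min()), x.max()))
            if int((x <= c).sum()) < 3 or n - int((x <= c).sum()) < 3:
                c = float(vertex)
            breakpoint_x = c
    else:
        breakpoint_x = float(breakpoint)
        nl = int((x <= breakpoint_x).sum())
        if nl < 3 or n - nl < 3:
            raise ValueError("supplied breakpoint leaves < 3 points on one side")

    res, n_low, n_high = _interrupted_fit(x, y, breakpoint_x)
    slope_low, slope_high = float(res.params[1]), float(res.params[3])
    z_low = slope_low / float(res.bse[1])
    z_high = slope_high / float(res.bse[3])
    df = res.df_resid
    p_low = 2 * stats.t.sf(abs(z_low), df)
    p_high = 2 * stats.t.sf(abs(z_high), df)

    both_sig = p_low < alpha and p_high < alpha
    if both_sig and slope_low * slope_high < 0:
        verdict = "u_shape_confirmed"
    elif both_sig and slope_low * slope_high > 0:
        verdict = "monotonic"
    else:
        verdict = "inconclusive"
    return TwoLinesResult(
        breakpoint_x=breakpoint_x,
        slope_low=slope_low, z_low=float(z_low), p_low=float(p_low),
        slope_high=slope_high, z_high=float(z_high), p_high=float(p_high),
        n_low=n_low, n_high=n_high, verdict=verdict, note=note,
    )


@dataclass
class BayesTResult:
    """Default Bayesian two-sample t-test result."""

    t_statistic: float
    n1: int
    n2: int
    cauchy_scale_r: float
    bf10: float
    bf01: float
    effect_size_d: float
    d_ci95: tuple[float, float]


def _jzs_integrand(g: float, t: float, N: float, nu: float, r: float) -> float:
    a = 1.0 + N * g * r * r
    return (
        a ** -0.5
        * (1.0 + t * t / (nu * a)) ** (-(nu + 1.0) / 2.0)
        * (2.0 * math.pi) ** -0.5
        * g ** -1.5
        * math.exp(-1.0 / (2.0 * g))
    )


def jzs_bayes_factor(t: float, n1: int, n2: int, r: float = DEFAULT_CAUCHY_SCALE) -> BayesTResult:
    """JZS Bayes factor for a two-sided independent-samples t-test.

    BF10 is the ratio of the marginal likelihood under a Cauchy(0, r) prior
    on the standardized effect (integrated over the variance scale g with
    its inverse-chi-square weight) to the point-null likelihood. Evaluated
    by adaptive quadrature after mapping g = u/(1-u) onto (0, 1); relative
    tolerance 1e-10.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if not (r > 0) or not math.isfinite(t):
        raise ValueError("need finite t and positive Cauchy scale r")
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2

    def transformed(u: float) -> float:
        g = u / (1.0 - u)
        return _jzs_integrand(g, t, N, nu, r) / (1.0 - u) ** 2

    numerator, err = integrate.quad(transformed, 0.0, 1.0,
                                    epsabs=0.0, epsrel=1e-10, limit=200)
    if not math.isfinite(numerator) or numerator <= 0 or err > 1e-6 * numerator:
        raise RuntimeError(
            f"JZS quadrature did not converge (value={numerator}, err={err})"
        )
    null_likelihood = (1.0 + t * t / nu) ** (-(nu + 1.0) / 2.0)
    bf10 = numerator / null_likelihood
    d, ci = cohens_d_from_t(t, n1, n2)
    return BayesTResult(
        t_statistic=float(t), n1=int(n1), n2=int(n2), cauchy_scale_r=float(r),
        bf10=bf10, bf01=1.0 / bf10, effect_size_d=d, d_ci95=ci,
    )


def cohens_d_from_t(t: float, n1: int, n2: int) -> tuple[float, tuple[float, float]]:
    """Cohen's d from an independent-samples t, with a 95% normal CI.

    d = t * sqrt(1/n1 + 1/n2); SE^2 = (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    d = t * math.sqrt(1 / n1 + 1 / n2)
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2)))
    return d, (d - 1.96 * se, d + 1.96 * se)


def _check_groups(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    return a, b


def student_t(group_a, group_b) -> tuple[float, float, float]:
    """Pooled-variance independent t-test: (t, df, two-sided p)."""
    a, b = _check_groups(group_a, group_b)
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    a, b = _check_groups(group_a, group_b)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def variance_ratio_test(older, younger) -> tuple[float, float]:
    """Variance-ratio F test: F = s²_older / s²_younger, two-sided p."""
    older = np.asarray(older, dtype=float)
    younger = np.asarray(younger, dtype=float)
    if len(older) < 2 or len(younger) < 2:
        raise ValueError("both groups need n >= 2")
    v_y = np.var(younger, ddof=1)
    if v_y == 0:
        raise ValueError("zero variance in the younger (denominator) group")
    F = float(np.var(older, ddof=1) / v_y)
    df1, df2 = len(older) - 1, len(younger) - 1
    cdf = stats.f.cdf(F, df1, df2)
    p = float(2 * min(cdf, 1 - cdf))
    return F, min(p, 1.0)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R²_j).

    Each column is regressed on the others plus an intercept. Perfectly
    collinear columns come back infinite; the conventional concern
    threshold is VIF > 5.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 design columns")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs n > number of columns")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(design[col].to_numpy(dtype=float), others).fit().rsquared
        out[col] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def association(x, y) -> dict:
    """Simple linear association: Pearson r, OLS slope, p, adjusted R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("association needs n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue ** 2
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "p": float(res.pvalue),
        "adjusted_r2": float(adj_r2),
        "n": n,
    }


def paired_t(left, right) -> tuple[float, float, float]:
    """Paired t-test (one-sample t on left - right differences)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) != len(right) or len(left) < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    if np.var(left - right, ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    res = stats.ttest_rel(left, right)
    return float(res.statistic), float(len(left) - 1), float(res.pvalue)
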