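"""Univariate statistics: force-deformation fits, reliability, RM-ANOVA.

Per-subject force-deformation curves are summarised by ordinary
least-squares linear and quadratic fits of mean deformation area on %MVC,
compared on adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) and labelled
with the conventional strength categories (weak 0.1-0.3, moderate
0.31-0.6, strong 0.61-0.9, very strong > 0.9).

Test-retest reliability across trials is an intraclass correlation from the
two-way ANOVA mean squares; ICC(2,1) (random trials, absolute agreement,
single measures) is reported by default with ICC(3,1) (consistency) as the
alternative, each with a 95% F-distribution confidence interval and the
Fleiss categories (poor < 0.40, fair 0.40-0.60, good 0.60-0.74,
strong > 0.75).

The one-way repeated-measures ANOVA tests how deformation changes with
%MVC; Mauchly's test checks sphericity and, when violated (p < 0.05),
degrees of freedom are multiplied by the Greenhouse-Geisser epsilon.
Pairwise follow-ups are Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import MissingDataError, SpecError


# ---------------------------------------------------------------------------
# categorical boundaries (half-open so [0, 1] is covered without gaps)
# ---------------------------------------------------------------------------

def r2_category(adj_r2: float) -> str:
    if adj_r2 > 0.90:
        return "very strong"
    if adj_r2 >= 0.61:
        return "strong"
    if adj_r2 >= 0.31:
        return "moderate"
    if adj_r2 >= 0.10:
        return "weak"
    return "below-weak"


def icc_category(icc: float) -> str:
    if icc >= 0.75:
        return "strong"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


# ---------------------------------------------------------------------------
# per-subject force-deformation fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    adj_r2_linear: float
    adj_r2_quadratic: float
    selected: str  # "linear" | "quadratic"
    category: str
    coef_linear: np.ndarray
    coef_quadratic: np.ndarray

    @property
    def adj_r2_selected(self) -> float:
        return self.adj_r2_linear if self.selected == "linear" else self.adj_r2_quadratic


def adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    y = np.asarray(y, dtype=float)
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise SpecError("response has zero variance")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    n = y.size
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_force_relationship(mvc_pct: np.ndarray, mean_area: np.ndarray) -> FitResult:
    """Linear vs quadratic OLS fit of mean area on %MVC.

    The shape with the larger adjusted R^2 is selected, ties going to the
    linear fit (parsimony), and the strength category is read off the
    selected adjusted R^2.
    """
    x = np.asarray(mvc_pct, dtype=float)
    y = np.asarray(mean_area, dtype=float)
    if x.size != y.size or x.size < 4:
        raise SpecError("need >= 4 paired points for the quadratic fit")
    c1 = np.polyfit(x, y, 1)
    c2 = np.polyfit(x, y, 2)
    adj1 = adjusted_r2(y, np.polyval(c1, x), 1)
    adj2 = adjusted_r2(y, np.polyval(c2, x), 2)
    selected = "quadratic" if adj2 > adj1 else "linear"
    adj = adj2 if selected == "quadratic" else adj1
    return FitResult(
        adj_r2_linear=adj1,
        adj_r2_quadratic=adj2,
        selected=selected,
        category=r2_category(adj),
        coef_linear=c1,
        coef_quadratic=c2,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    category: str
    variant: str  # "ICC(2,1)" | "ICC(3,1)"
    icc_consistency: float


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of a subjects x trials matrix (two-way, no replication)."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_trials(
    measurements: np.ndarray, variant: str = "ICC(2,1)", alpha: float = 0.05
) -> ICCResult:
    """Test-retest ICC of a subjects x trials matrix.

    Two-way, single-measures ICC from the ANOVA mean squares with a 95%
    F-distribution confidence interval; absolute agreement (ICC(2,1)) by
    default, consistency (ICC(3,1)) on request. Requires >= 5 subjects,
    >= 2 trials and no missing cells.
    """
    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2 or data.shape[0] < 5 or data.shape[1] < 2:
        raise SpecError("need a subjects x trials matrix with >= 5 subjects, >= 2 trials")
    if np.isnan(data).any():
        raise MissingDataError("ICC requires complete subjects x trials data")
    n, k = data.shape
    msr, msc, mse = _anova_mean_squares(data)
    icc_c = (msr - mse) / (msr + (k - 1) * mse) if (msr + (k - 1) * mse) > 0 else 0.0
    denom_a = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_a = (msr - mse) / denom_a if denom_a > 0 else 0.0
    if msr <= mse and np.isclose(msr, mse, atol=1e-12) and np.allclose(
        data.mean(axis=1), data.mean()
    ):
        warnings.warn("zero between-subject variance; ICC set to 0", stacklevel=2)
        value = 0.0
        ci = (0.0, 0.0)
        cat = icc_category(0.0)
        return ICCResult(value, ci, cat, variant, 0.0)

    if variant == "ICC(3,1)":
        value = icc_c
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    elif variant == "ICC(2,1)":
        value = icc_a
        # McGraw & Wong (1996) Satterthwaite interval for ICC(A,1)
        if value >= 1.0 or mse == 0:
            ci = (value, value)
        else:
            a = k * value / (n * (1 - value))
            b = 1 + k * value * (n - 1) / (n * (1 - value))
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
            ci = (lower, upper)
    else:
        raise SpecError("variant must be 'ICC(2,1)' or 'ICC(3,1)'")
    return ICCResult(
        icc=float(value),
        ci95=(float(ci[0]), float(ci[1])),
        category=icc_category(float(value)),
        variant=variant,
        icc_consistency=float(icc_c),
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RMAnovaResult:
    f_stat: float
    df: tuple[float, float]
    p_value: float
    gg_epsilon: float
    sphericity_violated: bool
    mauchly_w: float
    mauchly_p: float
    pairwise_p: dict


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance matrix.

    epsilon = tr(S*)^2 / ((k - 1) tr(S*^2)), S* the condition covariance
    matrix centred in both directions; ranges over (1/(k-1), 1].
    """
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    s = np.cov(data, rowvar=False, ddof=1)
    p = np.eye(k) - np.ones((k, k)) / k
    s_star = p @ s @ p
    num = np.trace(s_star) ** 2
    den = (k - 1) * np.trace(s_star @ s_star)
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


def mauchly_test(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity W and its chi-square p-value.

    Computed on the (k-1)-dimensional orthonormal-contrast covariance; with
    two conditions sphericity holds trivially (W = 1, p = 1).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k == 2:
        return 1.0, 1.0
    # orthonormal contrasts: Helmert basis orthogonal to the unit vector
    q, _ = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[: k - 1]]).T)
    c = q[:, 1:].T  # (k-1, k)
    a = c @ np.cov(data, rowvar=False, ddof=1) @ c.T
    d = k - 1
    det = np.linalg.det(a)
    tr = np.trace(a)
    if tr <= 0 or det <= 0:
        return 0.0, 0.0
    w = det / (tr / d) ** d
    # Box's chi-square approximation with the second-order correction term
    f_corr = 1 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288 * ((n - 1) * d * f_corr) ** 2)
    )
    chi2 = -(n - 1) * f_corr * np.log(w)
    ddof = d * (d + 1) // 2 - 1
    p1 = sps.chi2.sf(chi2, ddof)
    p2 = sps.chi2.sf(chi2, ddof + 4)
    return float(w), float(p1 + w2 * (p2 - p1))


def rm_anova(values: np.ndarray, alpha: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA of a subjects x conditions matrix.

    When Mauchly's test rejects sphericity (p < alpha), both degrees of
    freedom are multiplied by the Greenhouse-Geisser epsilon. Pairwise
    condition differences are Bonferroni-corrected paired t-tests.
    """
    data = np.asarray(values, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise SpecError("need a subjects x conditions matrix with >= 2 conditions")
    if np.isnan(data).any():
        raise MissingDataError("RM-ANOVA requires complete data")
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_stat = 0.0 if ss_cond == 0 else np.inf
    else:
        f_stat = (ss_cond / df_cond) / ms_err

    w, p_mauchly = mauchly_test(data)
    eps = gg_epsilon(data)
    violated = p_mauchly < alpha
    df1 = df_cond * eps if violated else float(df_cond)
    df2 = df_err * eps if violated else float(df_err)
    if np.isinf(f_stat):
        p_value = 0.0
    elif f_stat == 0.0:
        p_value = 1.0
    else:
        p_value = float(sps.f.sf(f_stat, df1, df2))

    n_pairs = k * (k - 1) // 2
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            if np.allclose(data[:, i], data[:, j]):
                p_raw = 1.0
            else:
                p_raw = sps.ttest_rel(data[:, i], data[:, j]).pvalue
            pairwise[(i, j)] = min(1.0, float(p_raw) * n_pairs)
    return RMAnovaResult(
        f_stat=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=p_value,
        gg_epsilon=eps,
        sphericity_violated=bool(violated),
        mauchly_w=w,
        mauchly_p=p_mauchly,
        pairwise_p=pairwise,
    )
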