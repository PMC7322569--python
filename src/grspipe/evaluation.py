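"""Model evaluation: ROC/AUC with DeLong inference, quintile odds ratios,
trend/ANOVA/regression models for severity and onset, and a case-control
power calculator.

AUC is the Mann-Whitney statistic (ties counted 1/2); its variance and the
variance of a difference of correlated AUCs use the DeLong structural
components, with normal-approximation confidence intervals truncated to
[0, 1].  Quintile stratification compares each upper score quintile with the
lowest by a 2x2 Pearson chi-square, reporting the odds ratio with a Woolf
log-scale CI (Haldane-Anscombe 0.5 correction, flagged, when a cell is
empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ComputationError, ConfigError


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong inference
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    var: float
    n_cases: int
    n_controls: int
    curve: pd.DataFrame       # columns: fpr, tpr (monotone (0,0) -> (1,1))


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    diff: float
    z: float
    p: float


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: (auc, v10 over cases, v01 over controls)."""
    case = labels == 1
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ComputationError("both classes must be present")
    ranks_all = stats.rankdata(scores)
    v10 = (ranks_all[case] - stats.rankdata(scores[case])) / n0
    v01 = 1.0 - (ranks_all[~case] - stats.rankdata(scores[~case])) / n1
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels, alpha: float = 0.05) -> ROCResult:
    """AUC with DeLong variance and normal CI, plus the ROC curve points."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    auc, v10, v01 = _structural_components(s, y.astype(int))
    n1, n0 = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    # ROC curve: sweep thresholds from high to low
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1.0 - y_sorted)[distinct]
    curve = pd.DataFrame({"fpr": np.r_[0.0, fp / n0], "tpr": np.r_[0.0, tp / n1]})
    return ROCResult(auc=auc, ci_low=ci_low, ci_high=ci_high, var=float(var),
                     n_cases=n1, n_controls=n0, curve=curve)


def delong_paired_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong Z test for the difference of two correlated AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ConfigError("paired scores must cover the same samples")
    auc_a, v10a, v01a = _structural_components(a, y)
    auc_b, v10b, v01b = _structural_components(b, y)
    n1, n0 = len(v10a), len(v01a)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / n1 if n1 > 1 else 0.0) \
        + (np.var(d01, ddof=1) / n0 if n0 > 1 else 0.0)
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, diff=float(diff),
                        z=float(z), p=p)


def auc_increment_test(outcome, covariate_matrix, score) -> DeLongResult:
    """Does a score add AUC beyond covariates?  Paired DeLong on fitted probs.

    Fits logistic ``outcome ~ covariates`` and ``outcome ~ covariates +
    score`` on the same samples and compares the two predicted-probability
    vectors; ``auc_a`` is the augmented model.  An empty covariate set
    reduces to comparing the score against a constant baseline.
    """
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    if covariate_matrix is None or np.size(covariate_matrix) == 0:
        cov = np.empty((len(y), 0))
    else:
        cov = np.asarray(covariate_matrix, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    x_base = sm.add_constant(cov, has_constant="add")
    x_full = np.column_stack([x_base, s])
    try:
        fit_base = sm.GLM(y, x_base, family=sm.families.Binomial()).fit()
        fit_full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit()
    except Exception as exc:       # singular / non-convergence
        raise ComputationError(f"logistic fit failed: {exc}") from exc
    return delong_paired_test(fit_full.fittedvalues, fit_base.fittedvalues, y)


# ---------------------------------------------------------------------------
# Quintile odds ratios
# ---------------------------------------------------------------------------

def quintile_assign(scores, n_groups: int = 5) -> np.ndarray:
    """Group index (0-based, by ascending score) with near-equal sizes.

    Ties are broken by sample order after a stable sort, so equal scores go
    to the lower quintile first.
    """
    s = np.asarray(scores, dtype=float)
    order = np.argsort(s, kind="stable")
    groups = np.empty(len(s), dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        groups[chunk] = g
    return groups


def quintile_or(scores, outcome, n_groups: int = 5) -> pd.DataFrame:
    """Per-quintile odds ratios of a binary outcome versus the first quintile.

    Columns: quintile (1-based), n_pos, n_neg, odds_ratio, ci_low, ci_high,
    p (Pearson chi-square vs quintile 1), corrected (Haldane-Anscombe flag).
    The reference quintile has OR = 1 by definition.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(s) < n_groups:
        raise ConfigError(f"need at least {n_groups} samples")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ConfigError("outcome must be binary 0/1")
    groups = quintile_assign(s, n_groups)
    rows = []
    ref_pos = ref_neg = None
    for g in range(n_groups):
        sel = groups == g
        n_pos = int(y[sel].sum())
        n_neg = int((~(y[sel] == 1)).sum())
        if g == 0:
            ref_pos, ref_neg = n_pos, n_neg
            rows.append({"quintile": 1, "n_pos": n_pos, "n_neg": n_neg,
                         "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "corrected": False})
            continue
        cells = np.array([n_pos, n_neg, ref_pos, ref_neg], dtype=float)
        corrected = bool((cells == 0).any())
        adj = cells + (0.5 if corrected else 0.0)
        or_ = adj[0] * adj[3] / (adj[1] * adj[2])
        log_se = np.sqrt((1.0 / adj).sum())
        ci_low = float(np.exp(np.log(or_) - 1.959963984540054 * log_se))
        ci_high = float(np.exp(np.log(or_) + 1.959963984540054 * log_se))
        table = np.array([[n_pos, n_neg], [ref_pos, ref_neg]], dtype=float)
        p = _pearson_chi2_p(table)
        rows.append({"quintile": g + 1, "n_pos": n_pos, "n_neg": n_neg,
                     "odds_ratio": float(or_), "ci_low": ci_low,
                     "ci_high": ci_high, "p": p, "corrected": corrected})
    return pd.DataFrame(rows)


def _pearson_chi2_p(table: np.ndarray) -> float:
    """2x2 Pearson chi-square P (no continuity correction)."""
    total = table.sum()
    expect = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expect == 0).any():
        return np.nan
    chi2 = float(((table - expect) ** 2 / expect).sum())
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Trend, ANOVA and regression models
# ---------------------------------------------------------------------------

def ordinal_trend_test(scores, levels):
    """Linear-regression test of a score trend over ordered disease levels.

    ``levels`` are ordinal codes (e.g. 0 = control, 1 = case without renal
    disease, 2 = case with renal disease).  Returns ``(slope, p)`` from the
    Wald test of the slope.
    """
    s = np.asarray(scores, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if len(np.unique(lv)) < 2:
        raise ComputationError("at least two distinct levels are required")
    x = sm.add_constant(lv)
    fit = sm.OLS(s, x).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def two_way_anova_grs(scores, age_group, renal_group) -> pd.DataFrame:
    """Two-factor ANOVA of the score on age group, renal group + interaction.

    Sequential (type-I) sums of squares in the order age, renal, age x renal.
    If a design cell is empty the interaction is omitted and flagged.
    Returns a frame with rows age, renal, interaction and columns F, p,
    omitted.
    """
    s = np.asarray(scores, dtype=float)
    a = np.asarray(age_group, dtype=int)
    r = np.asarray(renal_group, dtype=int)
    if set(np.unique(a)) - {0, 1} or set(np.unique(r)) - {0, 1}:
        raise ConfigError("age_group and renal_group must be binary 0/1")
    if np.ptp(s) == 0:      # degenerate: no variance to partition
        return pd.DataFrame([{"term": t, "F": 0.0, "p": np.nan,
                              "omitted": False}
                             for t in ("age", "renal", "interaction")])
    cells = {(i, j): int(((a == i) & (r == j)).sum())
             for i in (0, 1) for j in (0, 1)}
    with_interaction = all(v > 0 for v in cells.values())

    def rss(design):
        fit = sm.OLS(s, design).fit()
        return fit.ssr, fit.df_resid

    one = np.ones_like(s)
    d0 = one[:, None]
    d_a = np.column_stack([one, a])
    d_ar = np.column_stack([one, a, r])
    rss0, _ = rss(d0)
    rss_a, _ = rss(d_a)
    rss_ar, df_ar = rss(d_ar)
    rows = []
    if with_interaction:
        d_full = np.column_stack([one, a, r, a * r])
        rss_full, df_full = rss(d_full)
        mse = rss_full / df_full
        seq = [("age", rss0 - rss_a), ("renal", rss_a - rss_ar),
               ("interaction", rss_ar - rss_full)]
        for name, ss in seq:
            f = ss / mse if mse > 0 else 0.0
            rows.append({"term": name, "F": float(f),
                         "p": float(stats.f.sf(f, 1, df_full)) if mse > 0 else np.nan,
                         "omitted": False})
    else:
        mse = rss_ar / df_ar
        for name, ss in [("age", rss0 - rss_a), ("renal", rss_a - rss_ar)]:
            f = ss / mse if mse > 0 else 0.0
            rows.append({"term": name, "F": float(f),
                         "p": float(stats.f.sf(f, 1, df_ar)) if mse > 0 else np.nan,
                         "omitted": False})
        rows.append({"term": "interaction", "F": np.nan, "p": np.nan,
                     "omitted": True})
    return pd.DataFrame(rows)


def glm_association(outcome, predictors: pd.DataFrame, family: str = "logistic",
                    interactions=()) -> pd.DataFrame:
    """General regression with named predictors and optional interactions.

    ``predictors`` is a DataFrame of numeric columns; ``interactions`` lists
    ``(col_a, col_b)`` pairs added as products.  Returns per-term beta, SE,
    Wald statistic and two-sided P, with a ``flagged`` column marking
    separation-suspect coefficients (logistic |beta| > 15).  A rank-deficient
    design raises an error naming the collinear terms.
    """
    if family not in ("logistic", "linear"):
        raise ConfigError("family must be 'logistic' or 'linear'")
    y = np.asarray(outcome, dtype=float)
    x = predictors.astype(float).copy()
    for a, b in interactions:
        x[f"{a}:{b}"] = x[a] * x[b]
    x.insert(0, "const", 1.0)
    mat = x.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify columns that do not increase rank
        bad = []
        running = np.empty((mat.shape[0], 0))
        for name, col in zip(x.columns, mat.T):
            cand = np.column_stack([running, col])
            if np.linalg.matrix_rank(cand) == running.shape[1]:
                bad.append(name)
            else:
                running = cand
        raise ComputationError(f"design matrix is rank-deficient; "
                               f"collinear term(s): {bad}")
    if family == "logistic":
        fit = sm.GLM(y, mat, family=sm.families.Binomial()).fit()
    else:
        fit = sm.OLS(y, mat).fit()
    out = pd.DataFrame({
        "term": x.columns, "beta": fit.params, "se": fit.bse,
        "stat": fit.params / fit.bse, "p": fit.pvalues,
        "flagged": (np.abs(fit.params) > 15) if family == "logistic" else False,
    }).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Case-control power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the allelic two-proportion power approximation."""

    or_allele: float
    raf: float            # control risk-allele frequency
    alpha: float          # two-sided significance level
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.or_allele <= 0:
            raise ConfigError("or_allele must be > 0")
        if not 0 < self.raf < 1:
            raise ConfigError("raf must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ConfigError("sample counts must be positive")


def case_control_power(spec: PowerSpec) -> float:
    """Power of the allelic two-proportion test at a per-allele odds ratio.

    Alleles are counted as 2N independent trials per group; the case
    risk-allele frequency implied by the odds ratio is
    ``p1 = p0 OR / (1 + p0 (OR - 1))``.  The null SE uses the count-weighted
    pooled frequency, the alternative SE the group frequencies:
    ``power = Phi((|p1 - p0| - z_{1-alpha/2} SE0) / SE1)``.
    """
    p0 = spec.raf
    p1 = p0 * spec.or_allele / (1.0 + p0 * (spec.or_allele - 1.0))
    m1 = 2.0 * spec.n_case
    m0 = 2.0 * spec.n_control
    pbar = (p1 * m1 + p0 * m0) / (m1 + m0)
    se0 = np.sqrt(pbar * (1.0 - pbar) * (1.0 / m1 + 1.0 / m0))
    se1 = np.sqrt(p1 * (1.0 - p1) / m1 + p0 * (1.0 - p0) / m0)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    d = abs(p1 - p0)
    # both rejection tails; the second term vanishes for any real effect and
    # makes the null (OR = 1) power equal alpha rather than alpha/2
    return float(stats.norm.cdf((d - z_crit * se0) / se1)
                 + stats.norm.cdf((-d - z_crit * se0) / se1))
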