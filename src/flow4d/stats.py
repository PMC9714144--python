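"""Cohort statistics: group comparisons, correlation, stepwise regression,
ROC/Youden, DeLong AUC comparison, nested logistic incremental chi-square,
and Bland-Altman / coefficient-of-variation reproducibility.

Group comparisons gate on Shapiro-Wilk normality (alpha 0.05 per group):
both groups normal -> two-sample t test, otherwise Mann-Whitney U. The
Bonferroni family level is reported as literal 0.05/m. Stepwise regression
follows a univariate screen at P < 0.05 with forward selection (entry
P < 0.05) plus backward elimination (removal P > 0.10). The DeLong test
uses the structural-components covariance estimator for correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison", "RegressionReport", "ROCReport",
    "group_compare", "bonferroni_alpha", "correlate", "stepwise_model",
    "roc_youden", "delong_compare", "nested_logistic", "bland_altman",
]


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    test: str              # 't' or 'mannwhitney'
    statistic: float
    p_value: float
    bonferroni_alpha: float
    n: tuple[int, int]
    shapiro_p: tuple[float, float]


def bonferroni_alpha(family_size: int, alpha: float = 0.05) -> float:
    """Family-wise level as literal alpha/m (display-round to 3 decimals)."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_size


def group_compare(table, variable: str, family_size: int = 1,
                  group_col: str = "group", equal_var: bool = True,
                  normality_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``normality_alpha`` -> two-sample t test
    (pooled variance by default); otherwise Mann-Whitney U. The reported
    ``bonferroni_alpha`` is 0.05/family_size.
    """
    df = table.df if hasattr(table, "df") else table
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = df.loc[df[group_col] == groups[0], variable].dropna().to_numpy(float)
    b = df.loc[df[group_col] == groups[1], variable].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    sw_a = sps.shapiro(a).pvalue if len(set(a)) > 1 else 0.0
    sw_b = sps.shapiro(b).pvalue if len(set(b)) > 1 else 0.0
    if sw_a > normality_alpha and sw_b > normality_alpha:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("degenerate variance in both groups")
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitney"
    return GroupComparison(
        variable=variable, test=test, statistic=float(stat), p_value=float(p),
        bonferroni_alpha=bonferroni_alpha(family_size),
        n=(len(a), len(b)), shapiro_p=(float(sw_a), float(sw_b)),
    )


def correlate(table, x: str, y: str) -> tuple[float, float]:
    """Pearson r and two-sided P over paired complete observations."""
    df = table.df if hasattr(table, "df") else table
    sub = df[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 paired complete observations")
    xa, ya = sub[x].to_numpy(float), sub[y].to_numpy(float)
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Univariate screen + stepwise multivariable regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    outcome: str
    ln_outcome: bool
    univariate: pd.DataFrame          # coef, ci_low, ci_high, p per candidate
    selected: pd.DataFrame            # final multivariable coefficients
    excluded: list[str] = field(default_factory=list)
    r_squared: float | None = None


def _ols_fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_model(table, outcome: str, candidates: list[str],
                   ln_outcome: bool = False,
                   screen_alpha: float = 0.05,
                   entry_alpha: float = 0.05,
                   removal_alpha: float = 0.10) -> RegressionReport:
    """Univariate screen (P < 0.05) then forward-with-backward stepwise OLS.

    Outcomes may be natural-log transformed (``ln_outcome=True``) so that
    residuals of skewed outcomes are closer to normal. Collinear survivors
    (pairwise |r| > 0.999) drop the later-entering duplicate with a warning.
    Returns coefficients with 95 % CIs for both stages, the excluded list
    and the final-model R^2.
    """
    df = (table.df if hasattr(table, "df") else table)
    cols = [outcome] + list(candidates)
    data = df[cols].dropna().astype(float)
    y = data[outcome].to_numpy()
    if ln_outcome:
        if np.any(y <= 0):
            raise ValueError("outcome must be positive for a log transform")
        y = np.log(y)

    rows = {}
    survivors = []
    for c in candidates:
        fit = _ols_fit(y, data[[c]])
        ci = fit.conf_int().loc[c]
        rows[c] = {"coef": fit.params[c], "ci_low": ci[0], "ci_high": ci[1],
                   "p": fit.pvalues[c]}
        if fit.pvalues[c] < screen_alpha:
            survivors.append(c)
    univariate = pd.DataFrame(rows).T

    # drop near-duplicate survivors (keep the earlier-entering one)
    import warnings as _warnings
    kept = []
    for c in survivors:
        dup = any(abs(np.corrcoef(data[c], data[k])[0, 1]) > 0.999 for k in kept)
        if dup:
            _warnings.warn(f"dropping collinear candidate '{c}'", stacklevel=2)
        else:
            kept.append(c)
    survivors = kept

    selected: list[str] = []
    if survivors:
        changed = True
        while changed:
            changed = False
            # forward entry: best candidate with P < entry_alpha
            best, best_p = None, entry_alpha
            for c in survivors:
                if c in selected:
                    continue
                fit = _ols_fit(y, data[selected + [c]])
                p = fit.pvalues[c]
                if p < best_p:
                    best, best_p = c, p
            if best is not None:
                selected.append(best)
                changed = True
            # backward elimination: remove worst with P > removal_alpha
            while len(selected) > 0:
                fit = _ols_fit(y, data[selected])
                pvals = fit.pvalues.drop("const")
                worst = pvals.idxmax()
                if pvals[worst] > removal_alpha:
                    selected.remove(worst)
                    changed = True
                else:
                    break

    if selected:
        fit = _ols_fit(y, data[selected])
        ci = fit.conf_int()
        sel_df = pd.DataFrame({
            "coef": fit.params.drop("const"),
            "ci_low": ci[0].drop("const"),
            "ci_high": ci[1].drop("const"),
            "p": fit.pvalues.drop("const"),
        })
        r2 = float(fit.rsquared)
    else:
        sel_df = pd.DataFrame(columns=["coef", "ci_low", "ci_high", "p"])
        r2 = None
    excluded = [c for c in candidates if c not in selected]
    return RegressionReport(
        outcome=outcome, ln_outcome=ln_outcome, univariate=univariate,
        selected=sel_df, excluded=excluded, r_squared=r2,
    )


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong
# ---------------------------------------------------------------------------

@dataclass
class ROCReport:
    predictor: str
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    youden: float
    direction: str                  # 'greater': positive if value >= threshold


def _auc_mwu(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via midranks (equivalent to the scaled Mann-Whitney U)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def roc_youden(table, predictor: str, label: str,
               direction: str = "auto") -> ROCReport:
    """Empirical ROC with the Youden-optimal operating threshold.

    Candidate cut-points are the observed predictor values; a subject is
    called positive when the (possibly sign-flipped) value >= threshold.
    ``direction='auto'`` orients the predictor so AUC >= 0.5. Ties in
    Youden's index prefer the point with higher specificity, then the
    higher threshold.
    """
    df = table.df if hasattr(table, "df") else table
    sub = df[[predictor, label]].dropna()
    scores = sub[predictor].to_numpy(float)
    y = sub[label].to_numpy(int)
    if len(np.unique(y)) != 2:
        raise ValueError("label must contain both classes")

    sign = 1.0
    if direction == "less" or (direction == "auto" and _auc_mwu(scores, y) < 0.5):
        sign = -1.0
    s = sign * scores
    auc = _auc_mwu(s, y)

    best = None
    for thr in np.unique(s):
        pred = s >= thr
        sens = np.count_nonzero(pred & (y == 1)) / np.count_nonzero(y == 1)
        spec = np.count_nonzero(~pred & (y == 0)) / np.count_nonzero(y == 0)
        j = sens + spec - 1.0
        key = (j, spec, thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    return ROCReport(
        predictor=predictor, auc=float(auc), threshold=float(sign * thr),
        sensitivity=float(sens), specificity=float(spec),
        youden=float(sens + spec - 1.0),
        direction="greater" if sign > 0 else "less",
    )


def _delong_structural(pos_a, neg_a, pos_b, neg_b):
    """Structural components V10/V01 for two paired predictors."""
    def components(pos, neg):
        n1, n0 = len(pos), len(neg)
        cmp = (pos[:, None] > neg[None, :]).astype(float)
        cmp += 0.5 * (pos[:, None] == neg[None, :])
        return cmp.mean(axis=1), cmp.mean(axis=0), cmp.mean()
    v10_a, v01_a, auc_a = components(pos_a, neg_a)
    v10_b, v01_b, auc_b = components(pos_b, neg_b)
    n1, n0 = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / n1 + s01 / n0
    return auc_a, auc_b, cov


def delong_compare(table, predictor_a: str, predictor_b: str, label: str):
    """DeLong test for two correlated AUCs on the same subjects.

    Returns (AUC_a, AUC_b, z, P). Identical predictors give delta AUC = 0
    and P = 1. Raises on a constant predictor (degenerate AUC variance).
    """
    df = table.df if hasattr(table, "df") else table
    sub = df[[predictor_a, predictor_b, label]].dropna()
    y = sub[label].to_numpy(int)
    if len(np.unique(y)) != 2:
        raise ValueError("label must contain both classes")
    a = sub[predictor_a].to_numpy(float)
    b = sub[predictor_b].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant predictor: degenerate AUC variance")
    auc_a, auc_b, cov = _delong_structural(a[y == 1], a[y == 0],
                                           b[y == 1], b[y == 0])
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-15:
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (the two-predictor formula with
    coincident predictors reduces to this)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _, _, cov = _delong_structural(scores[labels == 1], scores[labels == 0],
                                   scores[labels == 1], scores[labels == 0])
    return float(cov[0, 0])


# ---------------------------------------------------------------------------
# Nested logistic regression
# ---------------------------------------------------------------------------

def nested_logistic(table, label: str, base_vars: list[str], added_var: str):
    """Incremental value of one predictor over a base logistic model.

    Model chi-square is 2(ll_model - ll_null); the increment
    delta chi-square = chi2_full - chi2_base is referred to chi2(1).
    Returns a dict with chi2_base, chi2_full, delta_chi2, df, p and a
    ``separation`` flag when the ML fit did not converge cleanly.
    """
    df = table.df if hasattr(table, "df") else table
    cols = [label] + list(base_vars) + [added_var]
    sub = df[cols].dropna().astype(float)
    y = sub[label].to_numpy(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("label must be binary 0/1 with both classes present")

    def fit_chi2(varnames):
        X = sm.add_constant(sub[varnames], has_constant="add")
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return 2.0 * (res.llf - res.llnull), bool(res.mle_retvals.get("converged", True))

    chi2_base, conv_b = fit_chi2(list(base_vars))
    # a rank-deficient full design (added variable collinear with the base)
    # contributes no information: delta chi-square is 0 by construction
    X_full = sm.add_constant(sub[list(base_vars) + [added_var]], has_constant="add")
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(
            sm.add_constant(sub[list(base_vars)], has_constant="add")):
        chi2_full, conv_f = chi2_base, conv_b
    else:
        chi2_full, conv_f = fit_chi2(list(base_vars) + [added_var])
    delta = max(chi2_full - chi2_base, 0.0)
    return {
        "chi2_base": chi2_base,
        "chi2_full": chi2_full,
        "delta_chi2": delta,
        "df": 1,
        "p": float(sps.chi2.sf(delta, 1)),
        "separation": not (conv_b and conv_f),
    }


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------

def bland_altman(pairs) -> dict:
    """Bland-Altman agreement and coefficient of variation for repeated
    measurements.

    bias = mean difference, limits of agreement = bias +/- 1.96 SD(diff),
    CoV% = 100 x SD(diff) / grand mean of all measurements.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("need >= 2 measurement pairs")
    diff = pairs[:, 0] - pairs[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    grand_mean = float(pairs.mean())
    cov = 100.0 * sd / grand_mean if grand_mean != 0 else np.nan
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
        "cov_pct": cov,
    }
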