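"""SEM burden vs clinical phenotype: factor analysis, regression, group tests.

The per-sample SEM total ("burden") is the phenotype-associated summary
statistic. Three tools:

* :func:`famd` — factor analysis of mixed data: continuous variables are
  standardized, categorical variables one-hot encoded, scaled by
  1/sqrt(level proportion) and centered, then the joint matrix is
  decomposed by SVD. Reduces a clinical table to a few dimensions usable
  as regression predictors.
* :func:`regress_sem_burden` — age-adjusted Gaussian OLS of (by default
  log10-transformed) burden on dummy-coded clinical predictors, with
  fixed reference levels so coefficient signs are reproducible.
* :func:`compare_groups` — Shapiro-Wilk normality pre-check per group
  followed by the Wilcoxon rank-sum test, with medians and IQRs for
  boxplot-style summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: fixed dummy-coding reference levels, so coefficient signs are stable
REFERENCE_LEVELS = {"viral_status": "none", "tumor_grade": "I", "child_pugh": "A"}


@dataclass
class FactorResult:
    """Mixed-data factor decomposition of a phenotype table."""

    scores: pd.DataFrame          # samples x dims, column-centered
    explained_variance: np.ndarray  # eigenvalues, non-increasing
    explained_pct: np.ndarray       # percentages of total inertia
    total_inertia: float
    variable_assoc: pd.DataFrame    # variables x dims squared association
    dropped: list = field(default_factory=list)


@dataclass
class RegressionResult:
    """Coefficient table and metadata of one burden regression model."""

    table: pd.DataFrame  # index term; coef, stderr, p_value, ci_low, ci_high, p_bonferroni
    response: str
    transform: str
    covariates: list
    n_obs: int
    r_squared: float


def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col)


def famd(phenos: pd.DataFrame, n_dims: int = 5) -> FactorResult:
    """Factor analysis of mixed (continuous + categorical) data.

    Continuous columns are centered and scaled to unit variance
    (population sd), contributing inertia 1 each; a categorical column
    with L levels is one-hot encoded, each indicator divided by the
    square root of its level proportion and centered, contributing
    inertia L - 1. The SVD of the scaled matrix gives sample scores and
    per-dimension explained variances that sum to the total inertia.

    Constant columns are dropped with a warning; ``n_dims`` beyond the
    rank is truncated.
    """
    if phenos.shape[1] < 2 or phenos.shape[0] < 3:
        raise ValueError("famd needs >= 2 variables and >= 3 samples")
    n = phenos.shape[0]
    blocks, owners, dropped = [], [], []
    for name in phenos.columns:
        col = phenos[name]
        if col.nunique(dropna=False) <= 1:
            logger.warning("famd: dropping constant variable %r", name)
            dropped.append(name)
            continue
        if _is_continuous(col):
            x = col.to_numpy(dtype=float)
            z = (x - x.mean()) / x.std(ddof=0)
            blocks.append(z[:, None])
            owners.append([name])
        else:
            dummies = pd.get_dummies(col.astype(str))
            p = dummies.mean(axis=0).to_numpy()
            z = dummies.to_numpy(dtype=float) / np.sqrt(p)[None, :]
            z = z - z.mean(axis=0, keepdims=True)
            blocks.append(z)
            owners.append([name] * z.shape[1])
    if not blocks:
        raise ValueError("no non-constant variables")
    Z = np.hstack(blocks)
    owner_flat = [o for ow in owners for o in ow]
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eig = s**2
    rank = int(np.sum(eig > 1e-12))
    n_dims = min(n_dims, rank)
    total = float(eig.sum())
    scores = pd.DataFrame(
        U[:, :n_dims] * (s[:n_dims] * np.sqrt(n))[None, :],
        index=phenos.index,
        columns=[f"dim{i + 1}" for i in range(n_dims)],
    )
    # squared association of each variable with each dimension:
    # contribution of its columns to the dimension's inertia
    contrib = (Vt[:n_dims, :] ** 2) * eig[:n_dims, None]
    assoc = pd.DataFrame(
        0.0, index=[v for v in phenos.columns if v not in dropped],
        columns=scores.columns,
    )
    for j, var in enumerate(owner_flat):
        assoc.loc[var] += contrib[:, j]
    return FactorResult(
        scores=scores,
        explained_variance=eig[:n_dims],
        explained_pct=100.0 * eig[:n_dims] / total,
        total_inertia=total,
        variable_assoc=assoc,
        dropped=dropped,
    )


def _design_matrix(
    phenos: pd.DataFrame, predictors: list, covariates: list
) -> pd.DataFrame:
    cols = {}
    for name in list(predictors) + list(covariates):
        if name not in phenos.columns:
            raise KeyError(f"predictor {name!r} absent from phenotype table")
        col = phenos[name]
        if _is_continuous(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            ref = REFERENCE_LEVELS.get(name)
            levels = [str(v) for v in pd.unique(col.astype(str))]
            if ref is not None and str(ref) in levels:
                levels = [str(ref)] + sorted(set(levels) - {str(ref)})
            else:
                levels = sorted(levels)
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float).to_numpy()
    return pd.DataFrame(cols, index=phenos.index)


def regress_sem_burden(
    counts: pd.Series,
    phenos: pd.DataFrame,
    predictors: list,
    covariates: list = ("age",),
    transform: str = "log10",
) -> RegressionResult:
    """Age-adjusted OLS of (transformed) SEM burden on clinical predictors.

    Burden counts are large and right-skewed, so the default response is
    log10(count + 1); ``transform='identity'`` fits raw counts.
    Categorical predictors are dummy-coded against fixed reference
    levels (viral none, grade I, Child-Pugh A). A rank-deficient design
    raises an error naming the aliased terms. Bonferroni-adjusted
    p-values across the model's predictor terms are included.
    """
    if transform not in ("log10", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    common = counts.index.intersection(phenos.index)
    if len(common) < len(counts):
        missing = counts.index.difference(phenos.index)
        raise KeyError(f"samples without phenotypes: {list(missing[:5])}")
    y = counts.loc[common].to_numpy(dtype=float)
    if transform == "log10":
        y = np.log10(y + 1.0)
    X = _design_matrix(phenos.loc[common], list(predictors), list(covariates))
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        # identify aliased columns by incremental rank growth
        aliased, seen = [], []
        for c in exog.columns:
            seen.append(c)
            if np.linalg.matrix_rank(exog[seen].to_numpy()) < len(seen):
                aliased.append(c)
                seen.pop()
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "p_value": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    pred_terms = [t for t in table.index if t != "const" and not any(t == c for c in covariates)]
    m = len(pred_terms)
    table["p_bonferroni"] = np.nan
    table.loc[pred_terms, "p_bonferroni"] = np.minimum(
        table.loc[pred_terms, "p_value"] * m, 1.0
    )
    return RegressionResult(
        table=table,
        response=counts.name or "sem_total",
        transform=transform,
        covariates=list(covariates),
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def compare_groups(counts: pd.Series, groups: pd.Series, exact_max_n: int = 25) -> dict:
    """Two-group comparison of SEM totals with normality pre-check.

    Runs Shapiro-Wilk per group, then the two-sided Wilcoxon rank-sum
    (Mann-Whitney) test — exact when both groups are small and tie-free,
    otherwise the normal approximation with tie correction (flagged).
    Reports per-group medians and IQRs for boxplot-style summaries.
    """
    groups = groups.reindex(counts.index)
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) != 2:
        raise ValueError(f"compare_groups expects exactly 2 groups, got {levels}")
    arrs = {g: counts[groups == g].dropna().to_numpy(dtype=float) for g in levels}
    for g, a in arrs.items():
        if len(a) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    summary = {}
    for g, a in arrs.items():
        if len(np.unique(a)) > 1:
            sw_stat, sw_p = stats.shapiro(a)
        else:
            sw_stat, sw_p = np.nan, np.nan
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        summary[g] = {
            "n": int(len(a)),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "iqr": float(q3 - q1),
            "shapiro_stat": float(sw_stat) if np.isfinite(sw_stat) else None,
            "shapiro_p": float(sw_p) if np.isfinite(sw_p) else None,
        }
    a, b = arrs[levels[0]], arrs[levels[1]]
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (max(len(a), len(b)) <= exact_max_n) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return {
        "groups": list(levels),
        "summary": summary,
        "test": "wilcoxon_rank_sum",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": "exact" if use_exact else "normal_approximation",
        "tie_corrected": bool(has_ties and not use_exact),
    }
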