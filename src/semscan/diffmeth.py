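"""Paired differential methylation at site and region level.

Site level: per-probe paired t-test on tumor/peritumoral per-pair
differences, either plain or with empirical-Bayes variance moderation
(a hierarchical scaled-inverse-chi-square prior on the residual
variances, prior df and scale estimated by moments from the observed
variance distribution). The effect size is

    delta = mean(control) - mean(case)

oriented so that loss of methylation in the tumor gives positive delta.

Region level: site p-values combined per region (Fisher's chi-square by
default, Stouffer's z optionally); the region delta is the mean of its
member-site deltas.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix

logger = logging.getLogger(__name__)

ADJUST_METHODS = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}
COMBINE_METHODS = ("fisher", "stouffer")

SITE_COLUMNS = (
    "mean_control", "mean_case", "delta", "n_pairs",
    "statistic", "p_value", "adjusted_p", "degenerate",
)


@dataclass
class SiteDMResult:
    """Per-probe paired-test results; ``table`` indexed by probe id."""

    table: pd.DataFrame
    method: str
    adjust_method: str
    prior_df: float | None = None
    prior_var: float | None = None


@dataclass
class RegionDMResult:
    """Per-region combined p-values; ``table`` indexed by region id."""

    table: pd.DataFrame
    combine_method: str
    adjust_method: str


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting point for the monotone trigamma
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moments fit of the scaled-inverse-chi-square variance prior.

    Matches the mean and variance of log(s^2) against its theoretical
    moments under s^2 ~ s0^2 * F(df, d0); returns (d0, s0^2). d0 = inf
    means no excess spread (complete shrinkage to s0^2).
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    s2 = s2[ok]
    df = df[ok]
    z = np.log(s2)
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(np.mean(polygamma(1, df / 2.0)))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0 = float(np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def paired_site_test(
    case: BetaMatrix,
    control: BetaMatrix,
    pairs: dict | pd.Series,
    method: str = "plain",
    adjust: str = "benjamini_hochberg",
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> SiteDMResult:
    """Per-probe paired test of case vs control methylation.

    Parameters
    ----------
    pairs
        Mapping case sample id -> control sample id; every case sample
        must have exactly one partner present in ``control``.
    method
        'plain' for the textbook paired t-test; 'moderated' shrinks the
        per-probe variances toward a common prior (empirical Bayes) and
        adds the prior df to the residual df.

    Probes with zero variance of the differences are flagged
    ``degenerate`` and reported with p = 1.
    """
    if method not in ("plain", "moderated"):
        raise ValueError(f"unknown method {method!r}")
    pairs = dict(pairs)
    unpaired = [s for s in case.sample_ids if s not in pairs]
    if unpaired:
        raise ValueError(f"case samples without a control partner: {unpaired[:5]}")
    missing_ctrl = [pairs[s] for s in case.sample_ids if pairs[s] not in control.sample_ids]
    if missing_ctrl:
        raise ValueError(f"paired control samples absent: {missing_ctrl[:5]}")
    probes = case.probe_ids.intersection(control.probe_ids)
    cs = case.values.loc[probes].to_numpy(dtype=float)
    ct = control.values.loc[probes, [pairs[s] for s in case.sample_ids]].to_numpy(dtype=float)
    d = ct - cs  # control minus case, per pair
    complete = ~np.isnan(d)
    n = complete.sum(axis=1)
    if (n < 2).all():
        raise ValueError("no probe has >= 2 complete pairs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dbar = np.nanmean(d, axis=1)
        s2 = np.nanvar(d, axis=1, ddof=1)
        mean_control = np.nanmean(ct, axis=1)
        mean_case = np.nanmean(cs, axis=1)
    df = (n - 1).astype(float)
    degenerate = (s2 <= 0) | (n < 2)
    if method != "moderated":
        prior_df = prior_var = None
    if method == "moderated":
        if prior_df is None:
            d0, s0 = _fit_variance_prior(s2[~degenerate], df[~degenerate])
        else:  # explicit prior (prior_df=0 reduces exactly to the plain test)
            d0 = float(prior_df)
            s0 = float(prior_var) if prior_var is not None else float(np.median(s2[~degenerate]))
        prior_df, prior_var = d0, s0
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_post = np.full_like(df, np.inf)
        else:
            s2_post = (d0 * s0 + df * s2) / (d0 + df)
            df_post = df + d0
    else:
        s2_post, df_post = s2, df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dbar / np.sqrt(s2_post / n)
    p = np.where(
        degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), np.where(df_post > 0, df_post, 1))
    )
    # infinite posterior df -> normal reference
    inf_df = np.isinf(df_post) & ~degenerate if method == "moderated" else np.zeros_like(degenerate)
    if np.any(inf_df):
        p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    t = np.where(degenerate, np.nan, t)
    table = pd.DataFrame(
        {
            "mean_control": mean_control,
            "mean_case": mean_case,
            "delta": mean_control - mean_case,
            "n_pairs": n,
            "statistic": t,
            "p_value": p,
            "adjusted_p": adjust_pvalues(p, adjust),
            "degenerate": degenerate,
        },
        index=probes,
    )
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("paired_site_test: %d probes with degenerate variance", n_deg)
    return SiteDMResult(table, method, adjust, prior_df, prior_var)


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    'benjamini_hochberg' is the standard step-up FDR procedure;
    'bonferroni' is min(m * p, 1).
    """
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjust method {method!r}; use {list(ADJUST_METHODS)}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=ADJUST_METHODS[method])[1]


def combine_region_pvalues(
    site_results: SiteDMResult,
    regions: pd.DataFrame,
    method: str = "fisher",
    adjust: str = "benjamini_hochberg",
    region_types: tuple | None = None,
) -> RegionDMResult:
    """Combine member-site p-values into one p-value per region.

    Fisher: X^2 = -2 * sum(ln p) against chi-square with 2m df.
    Stouffer: z = sum(z_i) / sqrt(m) with z_i = Phi^-1(1 - p_i); all
    member p = 1 gives z = -inf, reported as combined p = 1.
    Site p-values of exactly 0 are clamped to the smallest positive
    float and logged. The region delta is the mean of member deltas.
    """
    if method not in COMBINE_METHODS:
        raise ValueError(f"unknown combine method {method!r}")
    reg = regions if region_types is None else regions[regions["region_type"].isin(region_types)]
    st = site_results.table
    reg = reg[reg["probe_id"].isin(st.index)]
    if reg.empty:
        raise ValueError("no region has a tested site")
    tiny = np.finfo(float).tiny
    rows = []
    for (rid, rtype), sub in reg.groupby(["region_id", "region_type"], sort=True):
        p = st.loc[sub["probe_id"], "p_value"].to_numpy(dtype=float)
        deltas = st.loc[sub["probe_id"], "delta"].to_numpy(dtype=float)
        m = len(p)
        if np.any(p == 0):
            logger.info("combine_region_pvalues: clamping %d zero p in %s", int((p == 0).sum()), rid)
            p = np.maximum(p, tiny)
        if method == "fisher":
            x2 = -2.0 * np.sum(np.log(p))
            comb = float(stats.chi2.sf(x2, 2 * m))
            stat = x2
        else:
            z = stats.norm.isf(p)  # p=1 -> -inf; sum stays -inf, sf(-inf)=1
            zc = float(np.sum(z) / np.sqrt(m))
            comb = float(stats.norm.sf(zc))
            stat = zc
        comb = max(comb, tiny)  # keep combined p in (0, 1]
        rows.append(
            {
                "region_id": rid,
                "region_type": rtype,
                "statistic": stat,
                "combined_p": comb,
                "mean_delta": float(np.nanmean(deltas)),
                "n_sites": m,
            }
        )
    table = pd.DataFrame(rows).set_index("region_id")
    table["adjusted_p"] = adjust_pvalues(table["combined_p"].to_numpy(), adjust)
    return RegionDMResult(table, method, adjust)


def count_significant(
    results: SiteDMResult, alpha: float = 0.05, delta_threshold: float = 0.30
) -> dict:
    """Counts of significant sites and of those with |delta| strictly above a cut.

    Both inequalities are strict: adjusted p < alpha, |delta| > threshold.
    """
    t = results.table
    sig = t["adjusted_p"] < alpha
    large = sig & (t["delta"].abs() > delta_threshold)
    return {
        "n_tested": int(len(t)),
        "n_significant": int(sig.sum()),
        "n_significant_large_delta": int(large.sum()),
        "alpha": alpha,
        "delta_threshold": delta_threshold,
    }


def top_k_cluster(
    matrix: BetaMatrix,
    results: SiteDMResult,
    labels: pd.Series,
    k: int = 1000,
    linkage_method: str = "average",
):
    """Hierarchical clustering of samples on the top-k most significant sites.

    Euclidean distance, average linkage, 2-cluster cut. Returns
    (dendrogram leaf order, cluster assignment, misclassification count),
    where misclassification is minimised over the two cluster-to-label
    mappings. With fewer than k tested sites all sites are used (warned).
    """
    st = results.table.sort_values("p_value", kind="mergesort")
    if len(st) < k:
        logger.warning("top_k_cluster: only %d sites available (< k=%d)", len(st), k)
        k = len(st)
    top = st.index[:k]
    X = matrix.values.loc[top].to_numpy(dtype=float).T  # samples x sites
    # pairwise-complete is overkill here; fill residual missing with site means
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    Z = hierarchy.linkage(X, method=linkage_method, metric="euclidean")
    order = hierarchy.leaves_list(Z)
    assign = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    lab = labels.reindex(matrix.sample_ids).to_numpy()
    uniq = pd.unique(lab)
    if len(uniq) != 2:
        raise ValueError(f"expected 2 tissue labels, got {list(uniq)}")
    mis = min(
        int(np.sum((assign == 1) != (lab == uniq[0]))),
        int(np.sum((assign == 1) != (lab == uniq[1]))),
    )
    assignment = pd.Series(assign, index=matrix.sample_ids, name="cluster")
    return order, assignment, mis


def mds_embed(X, dims: int = 2, index=None) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of samples.

    ``X`` is a samples x features array (or a BetaMatrix, embedded by
    sample). Double-centers the squared Euclidean distance matrix and
    eigendecomposes; coordinates are centered. Identical samples map to
    identical coordinates; fully degenerate input yields zeros.
    """
    if isinstance(X, BetaMatrix):
        index = X.sample_ids
        arr = X.values.to_numpy(dtype=float).T
    else:
        arr = np.asarray(X, dtype=float)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    if np.isnan(arr).any():
        col_mean = np.nanmean(arr, axis=0)
        arr = np.where(np.isnan(arr), col_mean[None, :], arr)
    d2 = squareform(pdist(arr, metric="euclidean")) ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dims]
    w_top = np.clip(w[idx], 0.0, None)
    if np.all(w_top <= 1e-12):
        logger.warning("mds_embed: degenerate configuration; returning zeros")
        coords = np.zeros((n, dims))
    else:
        coords = v[:, idx] * np.sqrt(w_top)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)
    cols = [f"dim{i + 1}" for i in range(dims)]
    return pd.DataFrame(coords, index=index, columns=cols)
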