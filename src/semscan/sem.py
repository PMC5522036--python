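"""Stochastic epigenetic mutation (SEM) calling.

A SEM is a per-sample, per-locus methylation value lying *strictly*
outside the Tukey fences of a reference population at that locus:

    lower = Q1 - k * IQR,   upper = Q3 + k * IQR,   IQR = Q3 - Q1

with k = 3 by default ("extreme outlier" fences). Case/control samples
are scored against fences fit on the full reference; reference subjects
themselves are scored leave-one-out, each against fences refit on the
remaining N-1 subjects, so no subject contributes to its own fences.

Values exactly at a fence are not called; missing values are never
called. Direction is recorded: ``hyper`` for value > upper, ``hypo``
for value < lower.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix

logger = logging.getLogger(__name__)

QUANTILE_METHODS = ("linear", "tukey")

FENCE_COLUMNS = ("Q1", "Q3", "IQR", "lower", "upper", "n_support")


@dataclass
class ReferenceFences:
    """Per-probe quartiles and outlier fences fit on a reference population.

    ``table`` is indexed by probe id with columns Q1, Q3, IQR, lower,
    upper, n_support. Probes with fewer than ``min_support`` non-missing
    reference values are excluded (and logged) rather than imputed.
    """

    table: pd.DataFrame
    k: float
    quantile_method: str
    min_support: int

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class EpimutationCallSet:
    """Sparse SEM calls plus per-sample totals.

    ``calls`` has columns (probe_id, sample_id, direction); ``per_sample_total``
    is indexed by every scored sample (zero counts included).
    """

    calls: pd.DataFrame
    per_sample_total: pd.Series
    reference_mode: str = "external"

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    def samples_with_probe(self, probe_id) -> pd.Index:
        return pd.Index(
            self.calls.loc[self.calls["probe_id"] == probe_id, "sample_id"].unique()
        )


@dataclass
class SharedSemResult:
    """Probes epimutated in > ``fraction_threshold`` of cases and in zero controls."""

    probes: list
    genes: list
    fraction_threshold: float
    probe_table: pd.DataFrame
    gene_means: pd.DataFrame | None = None


def _tukey_hinges(sorted_rows: np.ndarray, n_valid: np.ndarray):
    """Lower/upper Tukey hinges per row of a row-sorted array (NaN sorted last).

    Hinge depth d = (floor((n + 1) / 2) + 1) / 2; the hinge is the mean of
    the order statistics at floor(d) and ceil(d) (1-based).
    """
    n = n_valid
    d = (np.floor((n + 1) / 2) + 1) / 2.0
    lo_f = np.floor(d).astype(int) - 1
    lo_c = np.ceil(d).astype(int) - 1
    rows = np.arange(sorted_rows.shape[0])
    q1 = 0.5 * (sorted_rows[rows, lo_f] + sorted_rows[rows, lo_c])
    # upper hinge: same depth from the top
    hi_f = n - 1 - lo_f
    hi_c = n - 1 - lo_c
    q3 = 0.5 * (sorted_rows[rows, hi_f] + sorted_rows[rows, hi_c])
    return q1, q3


def _row_quartiles(values: np.ndarray, method: str):
    """Per-row (Q1, Q3, n_support) of a 2-D array with NaN-aware handling."""
    if method not in QUANTILE_METHODS:
        raise ValueError(
            f"unknown quantile_method {method!r}; choose from {QUANTILE_METHODS}"
        )
    n_valid = np.sum(~np.isnan(values), axis=1)
    if method == "linear":
        with np.errstate(all="ignore"):
            q = np.nanquantile(values, [0.25, 0.75], axis=1, method="linear")
        return q[0], q[1], n_valid
    srt = np.sort(values, axis=1)  # NaN sort to the end
    safe_n = np.maximum(n_valid, 1)
    q1, q3 = _tukey_hinges(srt, safe_n)
    q1 = np.where(n_valid > 0, q1, np.nan)
    q3 = np.where(n_valid > 0, q3, np.nan)
    return q1, q3, n_valid


def fit_fences(
    reference: BetaMatrix,
    k: float = 3.0,
    quantile_method: str = "linear",
    min_support: int = 8,
    min_iqr: float = 0.0,
) -> ReferenceFences:
    """Fit per-probe quartiles and outlier fences on a reference population.

    Parameters
    ----------
    reference
        Reference beta matrix (e.g. normal tissue from healthy subjects).
    k
        Fence multiplier; 3 marks "extreme" outliers, 1.5 ordinary ones.
    quantile_method
        'linear' (R quantile type-7 equivalent) or 'tukey' (boxplot hinges).
    min_support
        Probes with fewer non-missing reference values are excluded and
        logged, not imputed.
    min_iqr
        Optional floor applied to the IQR before computing fences; 0 keeps
        the faithful rule where an IQR of zero makes any deviation a call.
    """
    if reference.shape[0] == 0 or reference.shape[1] == 0:
        raise ValueError("empty reference matrix: cannot fit fences")
    vals = reference.values.to_numpy(dtype=float)
    q1, q3, n_valid = _row_quartiles(vals, quantile_method)
    iqr = np.maximum(q3 - q1, min_iqr)
    table = pd.DataFrame(
        {
            "Q1": q1,
            "Q3": q3,
            "IQR": iqr,
            "lower": q1 - k * iqr,
            "upper": q3 + k * iqr,
            "n_support": n_valid,
        },
        index=reference.probe_ids,
    )
    low_support = table.index[table["n_support"] < min_support]
    if len(low_support):
        logger.info(
            "fit_fences: excluding %d probes with < %d reference values "
            "(first few: %s)",
            len(low_support),
            min_support,
            list(low_support[:5]),
        )
        table = table.drop(index=low_support)
    return ReferenceFences(table, float(k), quantile_method, int(min_support))


def call_sems(samples: BetaMatrix, fences: ReferenceFences) -> EpimutationCallSet:
    """Call SEMs: value strictly above the upper or below the lower fence.

    Probes without a fitted fence are excluded and logged. Values exactly
    at a fence, and missing values, are never called.
    """
    common = samples.probe_ids.intersection(fences.probe_ids)
    dropped = samples.probe_ids.difference(fences.probe_ids)
    if len(dropped):
        logger.info(
            "call_sems: %d probes have no fitted fence and are excluded", len(dropped)
        )
    vals = samples.values.loc[common].to_numpy(dtype=float)
    ftab = fences.table.loc[common]
    lower = ftab["lower"].to_numpy()[:, None]
    upper = ftab["upper"].to_numpy()[:, None]
    with np.errstate(invalid="ignore"):
        hyper = vals > upper
        hypo = vals < lower
    pi, si = np.nonzero(hyper | hypo)
    direction = np.where(hyper[pi, si], "hyper", "hypo")
    calls = pd.DataFrame(
        {
            "probe_id": common[pi],
            "sample_id": samples.sample_ids[si],
            "direction": direction,
        }
    )
    totals = (
        calls.groupby("sample_id").size().reindex(samples.sample_ids, fill_value=0)
    )
    totals.name = "sem_total"
    return EpimutationCallSet(calls, totals, reference_mode="external")


def call_sems_reference_loo(
    reference: BetaMatrix,
    k: float = 3.0,
    quantile_method: str = "linear",
    min_support: int = 8,
    min_iqr: float = 0.0,
) -> EpimutationCallSet:
    """Leave-one-out SEM calling within the reference population.

    One by one, each reference subject is held out and scored against
    fences refit on the remaining N-1 subjects.
    """
    n = reference.shape[1]
    if n < min_support + 1:
        raise ValueError(
            f"leave-one-out calling needs at least {min_support + 1} reference "
            f"subjects (min_support + 1); got {n}"
        )
    pieces = []
    totals = {}
    for j, sid in enumerate(reference.sample_ids):
        rest = reference.subset(samples=reference.sample_ids.delete(j))
        fences = fit_fences(
            rest, k=k, quantile_method=quantile_method,
            min_support=min_support, min_iqr=min_iqr,
        )
        one = reference.subset(samples=[sid])
        cs = call_sems(one, fences)
        pieces.append(cs.calls)
        totals[sid] = int(cs.per_sample_total.iloc[0])
    calls = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["probe_id", "sample_id", "direction"])
    )
    per_sample = pd.Series(totals, name="sem_total").reindex(reference.sample_ids)
    return EpimutationCallSet(calls, per_sample, reference_mode="leave_one_out")


def sem_chromosome_distribution(
    calls: EpimutationCallSet,
    annotation: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-chromosome SEM counts, optionally split by sample group.

    ``groups`` maps sample id -> group label; without it a single 'all'
    column is returned. Column sums equal the total number of calls per
    group (conservation).
    """
    if calls.n_calls == 0:
        cols = sorted(groups.unique()) if groups is not None else ["all"]
        return pd.DataFrame(0, index=pd.Index([], name="chromosome"), columns=cols)
    missing = set(calls.calls["probe_id"]) - set(annotation.index)
    if missing:
        raise KeyError(f"called probes missing from annotation: {sorted(missing)[:5]}")
    df = calls.calls.copy()
    df["chromosome"] = annotation.loc[df["probe_id"], "chromosome"].to_numpy()
    df["group"] = (
        groups.reindex(df["sample_id"]).to_numpy() if groups is not None else "all"
    )
    out = df.groupby(["chromosome", "group"]).size().unstack(fill_value=0)
    out.columns.name = None
    return out


def select_shared_sems(
    case_calls: EpimutationCallSet,
    control_calls: EpimutationCallSet,
    annotation: pd.DataFrame,
    fraction: float = 0.90,
    n_case: int | None = None,
) -> SharedSemResult:
    """Select probes epimutated in > ``fraction`` of cases and in zero controls.

    Both conditions are strict: a probe present in exactly ``fraction`` of
    case samples is not selected, and a single control carrier excludes a
    probe. Selected probes are mapped to gene symbols via the annotation.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction_threshold must lie in (0, 1)")
    n_case = n_case if n_case is not None else len(case_calls.per_sample_total)
    if case_calls.n_calls == 0:
        logger.warning("select_shared_sems: empty case call set")
        empty = pd.DataFrame(columns=["probe_id", "n_case", "case_fraction", "gene"])
        return SharedSemResult([], [], fraction, empty)
    case_counts = (
        case_calls.calls.drop_duplicates(["probe_id", "sample_id"])
        .groupby("probe_id")
        .size()
    )
    control_probes = set(control_calls.calls["probe_id"].unique())
    frac = case_counts / n_case
    keep = case_counts.index[(frac > fraction) & ~case_counts.index.isin(control_probes)]
    table = pd.DataFrame(
        {
            "probe_id": keep,
            "n_case": case_counts.loc[keep].to_numpy(),
            "case_fraction": frac.loc[keep].to_numpy(),
            "gene": annotation.loc[keep, "gene"].to_numpy(),
        }
    ).reset_index(drop=True)
    genes = sorted({g for g in table["gene"] if g})
    return SharedSemResult(list(keep), genes, fraction, table)


def region_group_means(
    matrix: BetaMatrix,
    regions: pd.DataFrame,
    groups: pd.Series,
    region_types: tuple = ("promoter", "gene_body"),
    gene_subset: list | None = None,
) -> pd.DataFrame:
    """Mean methylation per (gene, region type, sample group), missing-aware.

    Averages over all (probe in region) x (sample in group) entries,
    ignoring NaN. Regions with no probe present in the matrix are
    reported as NaN and logged.
    """
    rows = []
    reg = regions[regions["region_type"].isin(region_types)]
    if gene_subset is not None:
        reg = reg[reg["gene"].isin(gene_subset)]
    for (gene, rtype), sub in reg.groupby(["gene", "region_type"]):
        probes = [p for p in sub["probe_id"] if p in matrix.probe_ids]
        if not probes:
            logger.info("region_group_means: no probes in matrix for %s/%s", gene, rtype)
        for grp in pd.unique(groups):
            smp = groups.index[groups == grp]
            smp = [s for s in smp if s in matrix.sample_ids]
            if probes and smp:
                block = matrix.values.loc[probes, smp].to_numpy(dtype=float)
                mean = float(np.nanmean(block)) if not np.all(np.isnan(block)) else np.nan
            else:
                mean = np.nan
            rows.append({"gene": gene, "region_type": rtype, "group": grp, "mean": mean})
    return pd.DataFrame(rows)
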