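"""Probe/sample quality filtering applied before any analysis.

Three stages, mirroring common 450K practice:

1. drop probes overlapping SNPs, then probes on sex chromosomes
   (flags-first ordering; a probe carrying both flags counts under SNP);
2. Greedycut: iteratively remove the probe or sample with the largest
   fraction of unreliable entries (detection p >= threshold) until the
   matrix is clean or a dimension floor is reached;
3. mask remaining unreliable entries to missing.

"Unreliable" is read literally as detection p not below the threshold,
so p == T is unreliable (boundary masked). T defaults to 0.05.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BetaMatrix, FilterReport

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.05


def filter_flagged_probes(
    matrix: BetaMatrix, annotation: pd.DataFrame
) -> tuple[BetaMatrix, FilterReport]:
    """Remove SNP-overlapping probes first, then sex-chromosome probes.

    Probe order is preserved; the two removals are counted separately and
    a probe flagged both ways counts under the SNP rule (applied first).
    """
    missing = matrix.probe_ids.difference(annotation.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} matrix probes absent from annotation, e.g. "
            f"{list(missing[:5])}"
        )
    ann = annotation.loc[matrix.probe_ids]
    snp = ann["snp_overlap"].astype(bool).to_numpy()
    sex = ann["sex_chromosome"].astype(bool).to_numpy() & ~snp
    keep = ~(snp | sex)
    report = FilterReport(
        removed_snp_probes=int(snp.sum()), removed_sex_probes=int(sex.sum())
    )
    logger.info(
        "filter_flagged_probes: removed %d SNP-overlap and %d sex-chromosome probes",
        report.removed_snp_probes,
        report.removed_sex_probes,
    )
    return matrix.subset(probes=matrix.probe_ids[keep]), report


def greedycut(
    matrix: BetaMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_sample_fraction: float = 0.5,
    min_probes: int = 10,
) -> tuple[BetaMatrix, FilterReport]:
    """Iteratively remove the worst probe or sample until no entry is unreliable.

    At each step the row (probe) and column (sample) with the largest
    fraction of unreliable entries (detection p >= threshold) are found;
    the larger fraction is removed, ties broken probe-first then by lowest
    index. Stops when clean or when the dimension floors block further
    removal: at least ``min_sample_fraction`` of the input samples are
    kept, and at least ``min_probes`` probes (capped at half the input
    probes so tiny matrices can still be cleaned). Each removal strictly
    shrinks the matrix, so the loop terminates.
    """
    if matrix.detection_p is None:
        raise ValueError(
            "greedycut requires detection p-values; skip this stage explicitly "
            "when the matrix has none"
        )
    vals = matrix.values.copy()
    pvals = matrix.detection_p.copy()
    n_samples0 = vals.shape[1]
    floor_samples = int(np.ceil(min_sample_fraction * n_samples0))
    floor_probes = min(min_probes, int(np.ceil(0.5 * vals.shape[0])))
    report = FilterReport(unreliable_threshold=float(threshold))
    while True:
        unrel = pvals.to_numpy(dtype=float) >= threshold
        if not unrel.any():
            break
        row_frac = unrel.mean(axis=1)
        col_frac = unrel.mean(axis=0)
        ri = int(np.argmax(row_frac))
        ci = int(np.argmax(col_frac))
        # remove the worse of the two; tie -> probe (row) first
        can_row = vals.shape[0] > floor_probes
        can_col = vals.shape[1] > floor_samples
        take_row = row_frac[ri] >= col_frac[ci]
        if take_row and not can_row:
            take_row = False  # fall back to sample removal if possible
        elif not take_row and not can_col:
            take_row = True
        if take_row:
            if not can_row:
                logger.warning("greedycut: dimension floors reached; stopping dirty")
                break
            probe = vals.index[ri]
            report.removal_log.append(("probe", probe, float(row_frac[ri])))
            report.greedycut_removed_probes += 1
            logger.info(
                "greedycut: removing probe %s (%.1f%% unreliable)",
                probe, 100 * row_frac[ri],
            )
            vals = vals.drop(index=probe)
            pvals = pvals.drop(index=probe)
        else:
            if not can_col:
                logger.warning("greedycut: dimension floors reached; stopping dirty")
                break
            sample = vals.columns[ci]
            report.removal_log.append(("sample", sample, float(col_frac[ci])))
            report.greedycut_removed_samples += 1
            logger.info(
                "greedycut: removing sample %s (%.1f%% unreliable)",
                sample, 100 * col_frac[ci],
            )
            vals = vals.drop(columns=sample)
            pvals = pvals.drop(columns=sample)
    return BetaMatrix(vals, pvals), report


def mask_unreliable(
    matrix: BetaMatrix, threshold: float = DEFAULT_THRESHOLD
) -> BetaMatrix:
    """Set entries with detection p >= threshold to missing; shape unchanged."""
    if matrix.detection_p is None:
        raise ValueError("mask_unreliable requires detection p-values")
    mask = matrix.detection_p.to_numpy(dtype=float) >= threshold
    vals = matrix.values.copy()
    arr = vals.to_numpy(dtype=float)
    arr[mask] = np.nan
    n = int(mask.sum())
    if n:
        logger.info("mask_unreliable: masked %d entries at p >= %g", n, threshold)
    return BetaMatrix(
        pd.DataFrame(arr, index=vals.index, columns=vals.columns),
        matrix.detection_p.copy(),
    )
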