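"""Readers and writers for the package's plain-text formats.

Beta matrices travel as TSV (probes as rows, header = sample ids) with
an optional sibling detection-p TSV of identical layout; annotation and
region catalogs as TSV; phenotypes as CSV; SEM calls additionally as
BED. All internal genomic positions are 1-based inclusive; conversion
to 0-based half-open happens only at the BED boundary.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BetaMatrix,
    SchemaError,
    validate_annotation,
    validate_phenotypes,
    validate_regions,
)


def read_beta_matrix(path, detection_p_path=None) -> BetaMatrix:
    """Read a beta matrix TSV (+ optional detection-p TSV of identical layout).

    Values outside [0, 1] are a hard error naming the offending probe and
    sample; malformed (ragged) rows are rejected with their line number.
    """
    path = Path(path)
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed TSV ({exc})") from exc
    non_numeric = values.columns[values.dtypes == object]
    for col in non_numeric:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            row = values.index.get_loc(bad.idxmax()) + 2  # header line is 1
            raise SchemaError(
                f"{path}: non-numeric value {values[col][bad].iloc[0]!r} "
                f"at line {row}, column {col!r}"
            )
        values[col] = coerced
    det = None
    if detection_p_path is not None:
        det = pd.read_csv(detection_p_path, sep="\t", index_col=0)
    return BetaMatrix(values, det)


def write_beta_matrix(matrix: BetaMatrix, path, detection_p_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")
    if detection_p_path is not None and matrix.detection_p is not None:
        matrix.detection_p.to_csv(
            detection_p_path, sep="\t", index_label="probe_id", float_format="%.10g"
        )


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                      na_values=[], dtype={"gene": str, "gene_region": str})
    for c in ("snp_overlap", "sex_chromosome"):
        if c in ann.columns and ann[c].dtype == object:
            ann[c] = ann[c].astype(str).str.lower().isin(("true", "1", "yes"))
    ann["position"] = ann["position"].astype(int)
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe_id")


def read_regions(path) -> pd.DataFrame:
    reg = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return validate_regions(reg)


def write_regions(regions: pd.DataFrame, path) -> None:
    regions.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    phenos = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[""])
    for c in ("alcoholic_liver_disease", "nash", "cirrhosis"):
        if c in phenos.columns and phenos[c].dtype == object:
            phenos[c] = phenos[c].astype(str).str.lower().isin(("true", "1", "yes"))
    return validate_phenotypes(phenos)


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(path, index_label="sample_id")


def write_calls(callset, path) -> None:
    """Sparse (probe, sample, direction) TSV of SEM calls."""
    callset.calls.to_csv(path, sep="\t", index=False)


def write_totals(callset, path) -> None:
    callset.per_sample_total.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def write_bed(calls: pd.DataFrame, annotation: pd.DataFrame, path) -> None:
    """Export calls as BED: 0-based half-open, name = probe|direction, score 0.

    A probe at 1-based position P becomes the interval [P-1, P).
    """
    pos = annotation.loc[calls["probe_id"], "position"].to_numpy(dtype=int)
    chrom = annotation.loc[calls["probe_id"], "chromosome"].to_numpy()
    bed = pd.DataFrame(
        {
            "chrom": chrom,
            "start": pos - 1,
            "end": pos,
            "name": calls["probe_id"].to_numpy()
            + "|" + calls["direction"].to_numpy(),
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_truth_table(truth, path) -> None:
    truth.injected_calls.to_csv(path, sep="\t", index=False)


def write_report(report: dict, path) -> None:
    path = Path(path)
    text = (
        json.dumps(_plain(report), indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(_plain(report), sort_keys=False)
    )
    path.write_text(text)


def _plain(obj):
    """Recursively convert numpy/pandas scalars for YAML/JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (pd.Series,)):
        return _plain(obj.to_dict())
    return obj
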