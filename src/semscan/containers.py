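"""Core in-memory containers shared across the package.

The package works on methylation *beta values*: per-probe, per-sample
methylated fractions in [0, 1] as produced by Infinium 450K arrays.
Containers are thin wrappers around pandas objects with documented
schemas, validated at construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical annotation columns (manifest-style); extra columns are allowed
ANNOTATION_COLUMNS = (
    "chromosome",
    "position",
    "gene",
    "gene_region",
    "snp_overlap",
    "sex_chromosome",
)

#: canonical phenotype columns (clinical-table schema)
PHENOTYPE_COLUMNS = (
    "tissue_class",
    "pair_id",
    "age",
    "sex",
    "viral_status",
    "alcoholic_liver_disease",
    "nash",
    "cirrhosis",
    "child_pugh",
    "tumor_grade",
    "tumor_number",
)

TISSUE_CLASSES = ("reference", "peritumoral", "tumor")
VIRAL_LEVELS = ("none", "HBV", "HCV", "HBV+HCV")

#: region set labels of the region catalog
REGION_TYPES = ("tiling", "gene", "promoter", "gene_body", "island")


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with optional detection p-values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns = sample ids, entries in
        [0, 1] or NaN (missing).
    detection_p
        Optional DataFrame of the same shape: per-entry probability that
        the signal is indistinguishable from background. High values mark
        unreliable betas.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            raise SchemaError("duplicate probe ids in beta matrix")
        if not v.columns.is_unique:
            raise SchemaError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise SchemaError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if self.detection_p is not None:
            p = self.detection_p
            if p.shape != v.shape:
                raise SchemaError(
                    f"detection_p shape {p.shape} != values shape {v.shape}"
                )
            # align on labels, not positions
            self.detection_p = p.loc[v.index, v.columns]
            parr = self.detection_p.to_numpy(dtype=float)
            if np.any(((parr < 0) | (parr > 1)) & ~np.isnan(parr)):
                raise SchemaError("detection p-values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        """Return a new matrix restricted to the given probes/samples (order kept)."""
        v = self.values
        p = self.detection_p
        if probes is not None:
            v = v.loc[probes]
            p = p.loc[probes] if p is not None else None
        if samples is not None:
            v = v[samples]
            p = p[samples] if p is not None else None
        return BetaMatrix(v.copy(), p.copy() if p is not None else None)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a probe annotation table against the manifest-style schema.

    Index = probe id; required columns `chromosome`, `position` (1-based),
    `gene` ('' for intergenic), `gene_region` ('promoter' | 'body' | ''),
    `snp_overlap`, `sex_chromosome` (booleans).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise SchemaError(f"annotation missing columns: {missing}")
    if not annotation.index.is_unique:
        raise SchemaError("duplicate probe ids in annotation")
    if (annotation["position"] < 1).any():
        raise SchemaError("annotation positions must be 1-based (>= 1)")
    bad = set(annotation["gene_region"].unique()) - {"promoter", "body", ""}
    if bad:
        raise SchemaError(f"unknown gene_region labels: {sorted(bad)}")
    return annotation


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Check a region catalog: long table (region_id, region_type, probe_id, gene)."""
    for c in ("region_id", "region_type", "probe_id"):
        if c not in regions.columns:
            raise SchemaError(f"region catalog missing column {c!r}")
    bad = set(regions["region_type"].unique()) - set(REGION_TYPES)
    if bad:
        raise SchemaError(f"unknown region types: {sorted(bad)}")
    return regions


def validate_phenotypes(phenos: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table (index = sample id) against the clinical schema."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phenos.columns]
    if missing:
        raise SchemaError(f"phenotype table missing columns: {missing}")
    if not phenos.index.is_unique:
        raise SchemaError("duplicate sample ids in phenotype table")
    bad = set(phenos["tissue_class"].unique()) - set(TISSUE_CLASSES)
    if bad:
        raise SchemaError(f"unknown tissue classes: {sorted(bad)}")
    bad = set(phenos["viral_status"].dropna().unique()) - set(VIRAL_LEVELS)
    if bad:
        raise SchemaError(f"unknown viral_status levels: {sorted(bad)}")
    if (phenos["age"].dropna() <= 0).any():
        raise SchemaError("ages must be positive")
    return phenos


@dataclass
class FilterReport:
    """Counts of what a preprocessing step removed."""

    removed_snp_probes: int = 0
    removed_sex_probes: int = 0
    greedycut_removed_probes: int = 0
    greedycut_removed_samples: int = 0
    unreliable_threshold: float | None = None
    removal_log: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "removed_snp_probes": int(self.removed_snp_probes),
            "removed_sex_probes": int(self.removed_sex_probes),
            "greedycut_removed_probes": int(self.greedycut_removed_probes),
            "greedycut_removed_samples": int(self.greedycut_removed_samples),
            "unreliable_threshold": self.unreliable_threshold,
        }
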