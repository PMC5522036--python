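"""Synthetic 450K-style methylation cohorts with planted epimutations.

Emulates the three-population design of the SEM study: a normal-tissue
reference panel, plus paired peritumoral/tumor samples, with

* a three-class Beta mixture baseline per probe (hypomethylated,
  hemimethylated, hypermethylated) mirroring the bimodal-plus-
  intermediate shape of real array data;
* per-sample epimutation burdens drawn from a negative binomial whose
  mean depends on tissue class, age (exponential increase) and clinical
  covariates (multiplicative factors);
* epimutations injected by displacing the baseline value beyond the
  reference Tukey fences by at least ``spike_magnitude`` (clipped to
  [0, 1]), which guarantees detectability and a clean truth set;
* a "shared gene" plan: selected genes epimutated in more than a stated
  fraction of tumors and in zero peritumoral samples, promoters
  displaced up and gene bodies down;
* detection p-values: Uniform(0, 0.01) for reliable entries and
  Uniform(0.05, 1) for a small planted fraction of unreliable ones.

Everything is deterministic given the spec and seed, and every
injection is recorded in a :class:`TruthTable` so downstream calling
can be scored exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .sem import fit_fences

logger = logging.getLogger(__name__)

METH_CLASSES = ("hypo", "hemi", "hyper")

#: default clinical level frequencies of the emulated patient population
DEFAULT_CLINICAL_FREQS = {
    "sex": {"M": 0.768, "F": 0.232},
    "viral_status": {"none": 0.218, "HBV": 0.130, "HCV": 0.595, "HBV+HCV": 0.057},
    "alcoholic_liver_disease": {True: 0.044, False: 0.956},
    "nash": {True: 0.115, False: 0.885},
    "cirrhosis": {True: 0.870, False: 0.130},
    "child_pugh": {"A": 0.826, "B": 0.174},
    "tumor_grade": {"I": 0.042, "II": 0.856, "III": 0.102},
    "tumor_number": {1: 0.710, 2: 0.159, 3: 0.057, 4: 0.074},
}


@dataclass
class ProbePanelSpec:
    """Layout of the synthetic probe panel."""

    n_probes: int = 2000
    #: autosome labels with probe allocation fractions (sex probes carved out first)
    chromosomes: tuple = (
        ("chr1", 0.2), ("chr2", 0.2), ("chr3", 0.2), ("chr4", 0.2), ("chr5", 0.2),
    )
    #: proportions of (hypo, hemi, hyper) baseline probes, summing to 1
    methylation_class_mix: tuple = (0.4, 0.2, 0.4)
    #: per-class (a, b) shape parameters of the baseline Beta distribution
    beta_params: dict = field(
        default_factory=lambda: {"hypo": (2.0, 18.0), "hemi": (10.0, 10.0), "hyper": (18.0, 2.0)}
    )
    fraction_snp_overlap: float = 0.02
    fraction_sex_chromosome: float = 0.05
    genes_per_chromosome: int = 4
    probes_per_gene_promoter: int = 3
    probes_per_gene_body: int = 5
    chromosome_length: int = 1_000_000
    tiling_width: int = 100_000

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not self.chromosomes:
            raise ValueError("chromosome list must not be empty")
        if abs(sum(f for _, f in self.chromosomes) - 1.0) > 1e-9:
            raise ValueError("chromosome allocation fractions must sum to 1")
        if abs(sum(self.methylation_class_mix) - 1.0) > 1e-9:
            raise ValueError("methylation class mix must sum to 1")
        for frac in (self.fraction_snp_overlap, self.fraction_sex_chromosome):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        per_gene = self.probes_per_gene_promoter + self.probes_per_gene_body
        n_sex = round(self.fraction_sex_chromosome * self.n_probes)
        for label, f in self.chromosomes:
            m = round(f * (self.n_probes - n_sex))
            if self.genes_per_chromosome * per_gene > m:
                raise ValueError(
                    f"chromosome {label} cannot host {self.genes_per_chromosome} "
                    f"genes of {per_gene} probes within ~{m} probes"
                )


@dataclass
class CohortSpec:
    """Study conditions for the paired-cohort generator."""

    n_reference: int = 114
    n_pairs: int = 20
    seed: int = 0
    age_range: tuple = (40, 80)
    #: expected injected SEM count per tissue class; reference defaults to 0
    #: (reference burden arises naturally from Beta noise via leave-one-out)
    burden_mean: dict = field(
        default_factory=lambda: {"reference": 0.0, "peritumoral": 25.0, "tumor": 320.0}
    )
    burden_dispersion: float = 8.0  # negative-binomial size parameter
    #: multiplicative burden increase per year of age
    age_effect: float = 1.02
    #: "variable:level" -> multiplicative burden factor
    covariate_effects: dict = field(
        default_factory=lambda: {
            "viral_status:HBV": 2.0,
            "viral_status:HCV": 1.6,
            "viral_status:HBV+HCV": 2.5,
            "tumor_grade:II": 1.2,
            "tumor_grade:III": 1.8,
        }
    )
    #: genes epimutated in > shared_fraction of tumors, zero peritumoral;
    #: None auto-picks two panel genes, [] disables the plan
    shared_gene_plan: list | None = None
    shared_fraction: float = 0.95
    #: minimum absolute beta displacement past the fence for an injection
    spike_magnitude: float = 0.15
    #: global tumor-vs-peritumoral differential methylation: fraction of
    #: call-free probes (fences outside [0, 1]) shifted in every tumor
    #: sample, the per-probe shift magnitude range, and the fraction of
    #: shifted probes losing (rather than gaining) methylation
    dm_fraction: float = 0.8
    dm_shift_range: tuple = (0.10, 0.30)
    dm_loss_fraction: float = 0.8
    #: fraction of entries planted with a high detection p-value
    unreliable_fraction: float = 0.002
    clinical_freqs: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_FREQS))
    fence_k: float = 3.0
    quantile_method: str = "linear"

    def validate(self) -> None:
        if self.n_reference < 8:
            raise ValueError(
                "n_reference must be >= 8: quartiles need at least 8 "
                "non-missing reference values per probe"
            )
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if self.spike_magnitude <= 0:
            raise ValueError("spike_magnitude must be positive")
        if not 0 < self.shared_fraction < 1:
            raise ValueError("shared_fraction must lie in (0, 1)")


@dataclass
class TruthTable:
    """Ground truth of every injected epimutation."""

    injected_calls: pd.DataFrame  # probe_id, sample_id, direction
    per_sample_injected_count: pd.Series
    planted_shared_genes: list
    skipped: list = field(default_factory=list)  # (probe, sample, reason)
    #: probes given a consistent tumor methylation shift (probe_id, shift)
    planted_dm: pd.DataFrame | None = None


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:rem]] += 1
    return base


def generate_panel(spec: ProbePanelSpec, seed: int = 0):
    """Build a probe annotation table and region catalog.

    Returns ``(annotation, regions)``. Probes get 1-based positions on
    fixed-length chromosomes; sex-chromosome probes live on chrX; each
    autosome hosts ``genes_per_chromosome`` genes laid out as a promoter
    cluster followed by a gene-body cluster. The region catalog covers
    the four region sets used downstream: tiling windows, genes,
    promoters (doubling as CpG islands) and gene bodies.
    """
    spec.validate()
    rng = np.random.default_rng([int(seed), 101])
    n = spec.n_probes
    n_sex = round(spec.fraction_sex_chromosome * n)
    labels = [c for c, _ in spec.chromosomes]
    fracs = np.array([f for _, f in spec.chromosomes], dtype=float)
    alloc = _largest_remainder(n - n_sex, fracs)
    chrom_of = np.concatenate(
        [np.repeat(lab, k) for lab, k in zip(labels, alloc)] + [np.repeat("chrX", n_sex)]
    )
    probe_ids = np.array([f"cg{i + 1:07d}" for i in range(n)])
    position = np.zeros(n, dtype=int)
    gene = np.full(n, "", dtype=object)
    gene_region = np.full(n, "", dtype=object)
    per_gene = spec.probes_per_gene_promoter + spec.probes_per_gene_body
    regions = []
    for lab in labels + ["chrX"]:
        idx = np.flatnonzero(chrom_of == lab)
        if len(idx) == 0:
            continue
        pos = np.sort(rng.choice(spec.chromosome_length, size=len(idx), replace=False)) + 1
        position[idx] = pos
        # tiling windows of fixed width covering the chromosome
        win = (pos - 1) // spec.tiling_width
        for w in np.unique(win):
            for p in probe_ids[idx[win == w]]:
                regions.append(
                    {"region_id": f"{lab}:tile{w:03d}", "region_type": "tiling",
                     "probe_id": p, "gene": ""}
                )
        if lab == "chrX":
            continue  # genes on autosomes only
        stride = len(idx) // spec.genes_per_chromosome
        for g in range(spec.genes_per_chromosome):
            sym = f"G{lab[3:]}_{g + 1}"
            block = idx[g * stride : g * stride + per_gene]
            prom = block[: spec.probes_per_gene_promoter]
            body = block[spec.probes_per_gene_promoter :]
            gene[block] = sym
            gene_region[prom] = "promoter"
            gene_region[body] = "body"
            for p in probe_ids[block]:
                regions.append(
                    {"region_id": f"gene:{sym}", "region_type": "gene",
                     "probe_id": p, "gene": sym}
                )
            for p in probe_ids[prom]:
                regions.append(
                    {"region_id": f"prom:{sym}", "region_type": "promoter",
                     "probe_id": p, "gene": sym}
                )
                # promoter clusters double as CpG islands in this panel
                regions.append(
                    {"region_id": f"isl:{sym}", "region_type": "island",
                     "probe_id": p, "gene": sym}
                )
            for p in probe_ids[body]:
                regions.append(
                    {"region_id": f"body:{sym}", "region_type": "gene_body",
                     "probe_id": p, "gene": sym}
                )
    # baseline methylation classes: promoters hypo, bodies hyper (the
    # canonical genic pattern), everything else from the configured mix
    meth_class = np.array(
        rng.choice(METH_CLASSES, size=n, p=np.asarray(spec.methylation_class_mix)),
        dtype=object,
    )
    meth_class[gene_region == "promoter"] = "hypo"
    meth_class[gene_region == "body"] = "hyper"
    # SNP-overlap flags on non-genic autosomal probes only, so planted
    # gene signal survives preprocessing
    n_snp = round(spec.fraction_snp_overlap * n)
    eligible_snp = np.flatnonzero((gene == "") & (chrom_of != "chrX"))
    snp_idx = rng.choice(eligible_snp, size=min(n_snp, len(eligible_snp)), replace=False)
    snp_overlap = np.zeros(n, dtype=bool)
    snp_overlap[snp_idx] = True
    a = np.array([spec.beta_params[c][0] for c in meth_class])
    b = np.array([spec.beta_params[c][1] for c in meth_class])
    annotation = pd.DataFrame(
        {
            "chromosome": chrom_of,
            "position": position,
            "gene": gene,
            "gene_region": gene_region,
            "snp_overlap": snp_overlap,
            "sex_chromosome": chrom_of == "chrX",
            "meth_class": meth_class,
            "beta_a": a,
            "beta_b": b,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    region_df = pd.DataFrame(regions, columns=["region_id", "region_type", "probe_id", "gene"])
    return annotation, region_df


def _draw_betas(annotation: pd.DataFrame, n_cols: int, rng) -> np.ndarray:
    a = annotation["beta_a"].to_numpy(dtype=float)[:, None]
    b = annotation["beta_b"].to_numpy(dtype=float)[:, None]
    return rng.beta(a, b, size=(len(annotation), n_cols))


def _detection_p(shape, rng, unreliable_fraction: float, protected=None) -> np.ndarray:
    """Mostly-reliable detection p-values with a planted unreliable fraction.

    ``protected`` is a boolean mask of entries that must stay reliable
    (injected epimutations are never hidden behind a bad detection p)."""
    p = rng.uniform(0.0, 0.01, size=shape)
    bad = rng.random(shape) < unreliable_fraction
    if protected is not None:
        bad &= ~protected
    p[bad] = rng.uniform(0.05, 1.0, size=int(bad.sum()))
    return p


def generate_reference(
    panel: pd.DataFrame, n_reference: int, spec: CohortSpec
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Draw the reference population from the panel's baseline distributions.

    Returns the reference beta matrix and a phenotype table holding the
    assigned ages (tissue_class 'reference').
    """
    if n_reference < 8:
        raise ValueError(
            "n_reference must be >= 8: per-probe quartiles need at least 8 "
            "supporting reference values"
        )
    rng = np.random.default_rng([int(spec.seed), 211])
    sample_ids = [f"REF{i + 1:03d}" for i in range(n_reference)]
    vals = _draw_betas(panel, n_reference, rng)
    det = _detection_p(vals.shape, rng, spec.unreliable_fraction)
    matrix = BetaMatrix(
        pd.DataFrame(vals, index=panel.index, columns=sample_ids),
        pd.DataFrame(det, index=panel.index, columns=sample_ids),
    )
    lo, hi = spec.age_range
    phenos = pd.DataFrame(
        {
            "tissue_class": "reference",
            "pair_id": "",
            "age": rng.integers(lo, hi + 1, size=n_reference),
            "sex": rng.choice(
                list(spec.clinical_freqs["sex"]),
                p=list(spec.clinical_freqs["sex"].values()),
                size=n_reference,
            ),
            "viral_status": "none",
            "alcoholic_liver_disease": False,
            "nash": False,
            "cirrhosis": False,
            "child_pugh": "",
            "tumor_grade": "",
            "tumor_number": 0,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrix, phenos


def expected_burden(spec: CohortSpec, tissue_class: str, age: float, pheno: dict) -> float:
    """Expected injected-SEM count for one sample under the burden model."""
    mu = float(spec.burden_mean.get(tissue_class, 0.0))
    if mu <= 0:
        return 0.0
    age_center = 0.5 * (spec.age_range[0] + spec.age_range[1])
    mu *= spec.age_effect ** (age - age_center)
    for key, factor in spec.covariate_effects.items():
        var, _, level = key.partition(":")
        if str(pheno.get(var)) == level:
            mu *= factor
    return mu


def draw_burden_count(spec: CohortSpec, mu: float, rng) -> int:
    """Negative-binomial burden draw with mean mu and size = burden_dispersion."""
    if mu <= 0:
        return 0
    size = spec.burden_dispersion
    return int(rng.negative_binomial(size, size / (size + mu)))


def _sample_clinical(spec: CohortSpec, rng) -> dict:
    row = {}
    for var, freqs in spec.clinical_freqs.items():
        levels = list(freqs)
        p = np.array(list(freqs.values()), dtype=float)
        row[var] = levels[int(rng.choice(len(levels), p=p / p.sum()))]
    return row


def generate_paired_cohort(
    panel: pd.DataFrame, reference: BetaMatrix, spec: CohortSpec
) -> tuple[BetaMatrix, pd.DataFrame, TruthTable]:
    """Generate paired peritumoral/tumor samples with planted epimutations.

    Reference fences are fit once on the untouched reference matrix;
    every injected value is displaced strictly beyond them (by
    ``spike_magnitude`` before clipping to [0, 1]) and asserted to lie
    outside at generation time. Probes with no headroom are skipped and
    logged, never mis-recorded in the truth table.
    """
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 307])
    fences = fit_fences(
        reference, k=spec.fence_k, quantile_method=spec.quantile_method, min_support=8
    )
    ftab = fences.table
    lower = ftab["lower"]
    upper = ftab["upper"]

    n_pairs = spec.n_pairs
    peri_ids = [f"P{i + 1:03d}" for i in range(n_pairs)]
    tum_ids = [f"T{i + 1:03d}" for i in range(n_pairs)]
    sample_ids = peri_ids + tum_ids
    classes = ["peritumoral"] * n_pairs + ["tumor"] * n_pairs

    lo, hi = spec.age_range
    pheno_rows = []
    for i in range(n_pairs):
        clin = _sample_clinical(spec, rng)
        age = int(rng.integers(lo, hi + 1))
        for sid, tclass in ((peri_ids[i], "peritumoral"), (tum_ids[i], "tumor")):
            pheno_rows.append(
                {
                    "sample_id": sid,
                    "tissue_class": tclass,
                    "pair_id": f"PAIR{i + 1:03d}",
                    "age": age,
                    **clin,
                }
            )
    phenos = pd.DataFrame(pheno_rows).set_index("sample_id")
    phenos["alcoholic_liver_disease"] = phenos["alcoholic_liver_disease"].astype(bool)
    phenos["nash"] = phenos["nash"].astype(bool)
    phenos["cirrhosis"] = phenos["cirrhosis"].astype(bool)

    values = pd.DataFrame(
        _draw_betas(panel, len(sample_ids), rng), index=panel.index, columns=sample_ids
    )
    injected: list[tuple] = []
    skipped: list[tuple] = []

    # --- global tumor differential methylation (mainly loss), planted only
    # on call-free probes so it can never masquerade as a SEM ---
    call_free = ftab.index[(lower < 0.0) & (upper > 1.0)]
    n_dm = int(round(spec.dm_fraction * len(call_free)))
    dm_probes = (
        pd.Index(rng.choice(call_free, size=n_dm, replace=False)) if n_dm else pd.Index([])
    )
    if n_dm:
        mag = rng.uniform(*spec.dm_shift_range, size=n_dm)
        sign = np.where(rng.random(n_dm) < spec.dm_loss_fraction, -1.0, 1.0)
        shift = mag * sign
        block = values.loc[dm_probes, tum_ids].to_numpy()
        values.loc[dm_probes, tum_ids] = np.clip(block + shift[:, None], 0.0, 1.0)
    planted_dm = pd.DataFrame(
        {"probe_id": dm_probes, "shift": shift if n_dm else []}
    )

    def inject(probe, sample, direction) -> bool:
        if probe not in ftab.index:
            skipped.append((probe, sample, "no fence"))
            return False
        if direction == "hyper":
            v = min(1.0, upper[probe] + spec.spike_magnitude)
            ok = v > upper[probe]
        else:
            v = max(0.0, lower[probe] - spec.spike_magnitude)
            ok = v < lower[probe]
        if not ok:
            skipped.append((probe, sample, f"no {direction} headroom"))
            return False
        values.at[probe, sample] = v
        injected.append((probe, sample, direction))
        return True

    # --- shared-gene plan: > shared_fraction of tumors, zero peritumoral ---
    panel_genes = sorted({g for g in panel["gene"] if g})
    if spec.shared_gene_plan is None:
        planted_genes = panel_genes[:2]
    else:
        unknown = set(spec.shared_gene_plan) - set(panel_genes)
        if unknown:
            raise ValueError(f"shared_gene_plan genes not in panel: {sorted(unknown)}")
        planted_genes = list(spec.shared_gene_plan)
    n_carrier = min(n_pairs, int(np.floor(spec.shared_fraction * n_pairs)) + 1)
    planted_probe_mask = panel["gene"].isin(planted_genes)
    for sym in planted_genes:
        carriers = rng.choice(tum_ids, size=n_carrier, replace=False)
        sub = panel[panel["gene"] == sym]
        for probe, row in sub.iterrows():
            direction = "hyper" if row["gene_region"] == "promoter" else "hypo"
            for sid in carriers:
                inject(probe, sid, direction)

    # --- burden injections on probes outside the planted genes ---
    feasible = (upper < 1.0) | (lower > 0.0)
    eligible = ftab.index[
        feasible & ~planted_probe_mask.reindex(ftab.index, fill_value=False)
    ]
    hyper_ok = (upper.loc[eligible] < 1.0).to_numpy()
    hypo_ok = (lower.loc[eligible] > 0.0).to_numpy()
    for sid, tclass in zip(sample_ids, classes):
        mu = expected_burden(spec, tclass, phenos.at[sid, "age"], phenos.loc[sid].to_dict())
        m = draw_burden_count(spec, mu, rng)
        if m == 0:
            continue
        if m > len(eligible):
            logger.warning(
                "burden draw %d exceeds eligible probes (%d); capping", m, len(eligible)
            )
            m = len(eligible)
        pick = rng.choice(len(eligible), size=m, replace=False)
        for j in pick:
            can = [d for d, ok in (("hyper", hyper_ok[j]), ("hypo", hypo_ok[j])) if ok]
            if not can:
                skipped.append((eligible[j], sid, "no headroom"))
                continue
            direction = can[int(rng.integers(len(can)))] if len(can) > 1 else can[0]
            inject(eligible[j], sid, direction)

    truth_calls = pd.DataFrame(injected, columns=["probe_id", "sample_id", "direction"])
    # generation-time check: every injected value lies strictly outside fences
    if len(truth_calls):
        v = values.to_numpy()
        pidx = values.index.get_indexer(truth_calls["probe_id"])
        sidx = values.columns.get_indexer(truth_calls["sample_id"])
        vv = v[pidx, sidx]
        lo_f = lower.reindex(truth_calls["probe_id"]).to_numpy()
        up_f = upper.reindex(truth_calls["probe_id"]).to_numpy()
        outside = (vv > up_f) | (vv < lo_f)
        assert outside.all(), "internal error: injected value inside fences"
    per_sample = (
        truth_calls.groupby("sample_id").size().reindex(sample_ids, fill_value=0)
    )
    per_sample.name = "injected_count"
    protected = np.zeros(values.shape, dtype=bool)
    if len(truth_calls):
        protected[pidx, sidx] = True
    det = _detection_p(values.shape, rng, spec.unreliable_fraction, protected=protected)
    matrix = BetaMatrix(
        values, pd.DataFrame(det, index=values.index, columns=values.columns)
    )
    if skipped:
        logger.info("generate_paired_cohort: %d injections skipped", len(skipped))
    truth = TruthTable(truth_calls, per_sample, planted_genes, skipped, planted_dm)
    return matrix, phenos, truth
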