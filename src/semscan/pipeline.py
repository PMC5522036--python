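"""End-to-end orchestration of the SEM study design.

One config drives: input loading (real TSV/CSV files or the synthetic
cohort generator) -> preprocessing -> reference-fence SEM calling
(cases/controls against the full reference, reference subjects
leave-one-out) -> burden association -> paired differential methylation
-> shared-SEM candidate genes. Every stage echoes its dimensions and
parameters into a run report, and all outputs are deterministic given
the seed.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import diffmeth, io, preprocess, sem, synthetic

logger = logging.getLogger(__name__)

STAGE_ORDER = ("preprocess", "sem", "association", "diffmeth", "shared")


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run."""

    outdir: str = "semscan_run"
    seed: int = 0
    #: synthetic-generation overrides (panel/cohort spec fields); mutually
    #: exclusive with ``inputs``
    synthetic: dict | None = None
    #: real-input paths: reference, cases, controls, annotation, regions,
    #: phenotypes (+ optional *_detection_p siblings)
    inputs: dict | None = None
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    # stage parameters
    k: float = 3.0
    quantile_method: str = "linear"
    min_support: int = 8
    detection_threshold: float = 0.05
    run_greedycut: bool = True
    test_method: str = "plain"
    adjust_method: str = "benjamini_hochberg"
    combine_method: str = "fisher"
    alpha: float = 0.05
    delta_threshold: float = 0.30
    shared_fraction: float = 0.90
    #: sites used for hierarchical clustering; the default is scaled to the
    #: default 2,000-probe synthetic panel (top ~10% of sites) — full-array
    #: runs would use 1000
    top_k: int = 200
    make_plots: bool = False
    write_inputs: bool = False

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of 'synthetic' or 'inputs'"
            )
        if self.inputs is not None:
            for key in ("reference", "cases", "controls", "annotation"):
                p = self.inputs.get(key)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input {key!r} missing or absent: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_synthetic(config: PipelineConfig):
    over = dict(config.synthetic or {})
    panel_over = over.pop("panel", {})
    cohort_over = over.pop("cohort", {})
    if over:
        raise ValueError(f"unknown synthetic sections: {sorted(over)}")
    panel_spec = synthetic.ProbePanelSpec(**panel_over)
    cohort_over.setdefault("seed", config.seed)
    cohort_spec = synthetic.CohortSpec(**cohort_over)
    annotation, regions = synthetic.generate_panel(panel_spec, seed=config.seed)
    reference, ref_phenos = synthetic.generate_reference(
        annotation, cohort_spec.n_reference, cohort_spec
    )
    cases_controls, phenos, truth = synthetic.generate_paired_cohort(
        annotation, reference, cohort_spec
    )
    tumor_ids = phenos.index[phenos["tissue_class"] == "tumor"]
    peri_ids = phenos.index[phenos["tissue_class"] == "peritumoral"]
    cases = cases_controls.subset(samples=tumor_ids)
    controls = cases_controls.subset(samples=peri_ids)
    phenos_all = pd.concat([ref_phenos, phenos])
    return annotation, regions, reference, cases, controls, phenos_all, truth


def _load_inputs(config: PipelineConfig):
    inp = config.inputs
    annotation = io.read_annotation(inp["annotation"])
    regions = io.read_regions(inp["regions"]) if inp.get("regions") else None
    reference = io.read_beta_matrix(
        inp["reference"], inp.get("reference_detection_p")
    )
    cases = io.read_beta_matrix(inp["cases"], inp.get("cases_detection_p"))
    controls = io.read_beta_matrix(inp["controls"], inp.get("controls_detection_p"))
    phenos = io.read_phenotypes(inp["phenotypes"]) if inp.get("phenotypes") else None
    return annotation, regions, reference, cases, controls, phenos, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and return the run report.

    On stage failure, partial outputs are kept, a FAILED marker naming
    the stage is written, and the error is re-raised with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.as_dict(), "stages": {}}
    stage = "setup"
    try:
        if config.synthetic is not None:
            annotation, regions, reference, cases, controls, phenos, truth = (
                _build_synthetic(config)
            )
        else:
            annotation, regions, reference, cases, controls, phenos, truth = (
                _load_inputs(config)
            )
        if config.write_inputs:
            io.write_beta_matrix(reference, outdir / "reference.tsv",
                                 outdir / "reference_detection_p.tsv")
            io.write_beta_matrix(cases, outdir / "cases.tsv")
            io.write_beta_matrix(controls, outdir / "controls.tsv")
            io.write_annotation(annotation, outdir / "annotation.tsv")
            if regions is not None:
                io.write_regions(regions, outdir / "regions.tsv")
            if phenos is not None:
                io.write_phenotypes(phenos, outdir / "phenotypes.csv")
            if truth is not None:
                io.write_truth_table(truth, outdir / "truth.tsv")

        matrices = {"reference": reference, "cases": cases, "controls": controls}

        if config.stages.get("preprocess", True):
            stage = "preprocess"
            stage_rep = {}
            for name, mat in matrices.items():
                dims_in = mat.shape
                mat, flag_rep = preprocess.filter_flagged_probes(mat, annotation)
                gc_rep = None
                if config.run_greedycut and mat.detection_p is not None:
                    mat, gc_rep = preprocess.greedycut(mat, config.detection_threshold)
                if mat.detection_p is not None:
                    mat = preprocess.mask_unreliable(mat, config.detection_threshold)
                matrices[name] = mat
                stage_rep[name] = {
                    "dims_in": list(dims_in),
                    "dims_out": list(mat.shape),
                    **flag_rep.as_dict(),
                    **(gc_rep.as_dict() if gc_rep else {}),
                }
            report["stages"]["preprocess"] = stage_rep
        reference, cases, controls = (
            matrices["reference"], matrices["cases"], matrices["controls"]
        )

        fences = case_calls = control_calls = loo_calls = None
        if config.stages.get("sem", True):
            stage = "sem"
            fences = sem.fit_fences(
                reference, k=config.k, quantile_method=config.quantile_method,
                min_support=config.min_support,
            )
            case_calls = sem.call_sems(cases, fences)
            control_calls = sem.call_sems(controls, fences)
            loo_calls = sem.call_sems_reference_loo(
                reference, k=config.k, quantile_method=config.quantile_method,
                min_support=config.min_support,
            )
            io.write_calls(case_calls, outdir / "sem_calls_tumor.tsv")
            io.write_calls(control_calls, outdir / "sem_calls_peritumoral.tsv")
            io.write_calls(loo_calls, outdir / "sem_calls_reference_loo.tsv")
            totals = pd.concat(
                [loo_calls.per_sample_total, control_calls.per_sample_total,
                 case_calls.per_sample_total]
            )
            totals.to_frame().to_csv(outdir / "sem_totals.tsv", sep="\t",
                                     index_label="sample_id")
            io.write_bed(case_calls.calls, annotation, outdir / "sem_calls_tumor.bed")
            chrom_dist = sem.sem_chromosome_distribution(
                case_calls, annotation
            )
            chrom_dist.to_csv(outdir / "sem_chromosome_distribution.tsv", sep="\t")
            med = {
                "tumor": float(case_calls.per_sample_total.median()),
                "peritumoral": float(control_calls.per_sample_total.median()),
                "reference_loo": float(loo_calls.per_sample_total.median()),
            }
            iqr = {
                g: [float(t.per_sample_total.quantile(0.25)),
                    float(t.per_sample_total.quantile(0.75))]
                for g, t in (("tumor", case_calls), ("peritumoral", control_calls),
                             ("reference_loo", loo_calls))
            }
            report["stages"]["sem"] = {
                "n_fence_probes": int(len(fences.table)),
                "n_calls": {
                    "tumor": case_calls.n_calls,
                    "peritumoral": control_calls.n_calls,
                    "reference_loo": loo_calls.n_calls,
                },
                "median_sem_total": med,
                "iqr_sem_total": iqr,
            }

        if config.stages.get("association", True) and case_calls is not None:
            stage = "association"
            burdens = pd.concat(
                [case_calls.per_sample_total, control_calls.per_sample_total]
            )
            burdens.name = "sem_total"
            tissue = phenos["tissue_class"].reindex(burdens.index)
            tv_p = assoc_mod.compare_groups(burdens, tissue)
            stage_rep = {"tumor_vs_peritumoral": tv_p}
            all_burdens = pd.concat([burdens, loo_calls.per_sample_total])
            all_burdens.name = "sem_total"
            tissue_all = phenos["tissue_class"].reindex(all_burdens.index)
            peri_ref = assoc_mod.compare_groups(
                all_burdens[tissue_all != "tumor"],
                tissue_all[tissue_all != "tumor"],
            )
            stage_rep["peritumoral_vs_reference"] = peri_ref
            # factor reduction + age-adjusted regression per tissue class
            pair_phenos = phenos[phenos["tissue_class"] == "tumor"]
            clin_cols = ["age", "sex", "viral_status", "alcoholic_liver_disease",
                         "nash", "cirrhosis", "child_pugh", "tumor_grade",
                         "tumor_number"]
            fr = assoc_mod.famd(pair_phenos[clin_cols], n_dims=5)
            fr.scores.to_csv(outdir / "famd_scores.tsv", sep="\t")
            fr.variable_assoc.to_csv(outdir / "famd_variable_assoc.tsv", sep="\t")
            stage_rep["famd_explained_pct"] = [float(x) for x in fr.explained_pct]
            for tclass, calls in (("tumor", case_calls), ("peritumoral", control_calls)):
                cls_pheno = phenos[phenos["tissue_class"] == tclass]
                rr = None
                # grade dummies can be collinear with viral dummies in small
                # cohorts; fall back to viral status alone if so
                for predictors in (["viral_status", "tumor_grade"], ["viral_status"]):
                    try:
                        rr = assoc_mod.regress_sem_burden(
                            calls.per_sample_total.reindex(cls_pheno.index),
                            cls_pheno, predictors=predictors, covariates=["age"],
                        )
                        break
                    except ValueError as exc:
                        logger.warning(
                            "regression (%s) on %s failed: %s", tclass, predictors, exc
                        )
                        last_err = exc
                if rr is None:
                    stage_rep[f"regression_{tclass}"] = {"skipped": str(last_err)}
                    continue
                rr.table.to_csv(outdir / f"regression_{tclass}.tsv", sep="\t")
                stage_rep[f"regression_{tclass}"] = {
                    t: {"coef": float(r["coef"]), "p": float(r["p_value"])}
                    for t, r in rr.table.iterrows() if t != "const"
                }
            report["stages"]["association"] = stage_rep

        if config.stages.get("diffmeth", True):
            stage = "diffmeth"
            pairs = _pair_map(phenos, cases, controls)
            site = diffmeth.paired_site_test(
                cases, controls, pairs,
                method=config.test_method, adjust=config.adjust_method,
            )
            site.table.to_csv(outdir / "diffmeth_sites.tsv", sep="\t",
                              index_label="probe_id")
            counts = diffmeth.count_significant(
                site, alpha=config.alpha, delta_threshold=config.delta_threshold
            )
            stage_rep = {"site_counts": counts}
            if regions is not None:
                region = diffmeth.combine_region_pvalues(
                    site, regions, method=config.combine_method,
                    adjust=config.adjust_method,
                )
                region.table.to_csv(outdir / "diffmeth_regions.tsv", sep="\t")
                sig_by_type = (
                    region.table[region.table["adjusted_p"] < config.alpha]
                    .groupby("region_type").size()
                )
                tot_by_type = region.table.groupby("region_type").size()
                stage_rep["region_counts"] = {
                    t: {"significant": int(sig_by_type.get(t, 0)),
                        "tested": int(tot_by_type[t])}
                    for t in tot_by_type.index
                }
            shared_probes = cases.probe_ids.intersection(controls.probe_ids)
            both = pd.concat(
                [cases.values.loc[shared_probes], controls.values.loc[shared_probes]],
                axis=1,
            )
            from .containers import BetaMatrix
            combined = BetaMatrix(both)
            labels = phenos["tissue_class"].reindex(combined.sample_ids)
            order, assign, mis = diffmeth.top_k_cluster(
                combined, site, labels, k=config.top_k
            )
            stage_rep["topk_cluster_misclassified"] = int(mis)
            coords = diffmeth.mds_embed(combined)
            coords.to_csv(outdir / "mds_coordinates.tsv", sep="\t",
                          index_label="sample_id")
            report["stages"]["diffmeth"] = stage_rep
            if config.make_plots:
                from . import plots
                plots.volcano(site, outdir / "volcano.png")
                plots.mds_scatter(coords, labels, outdir / "mds.png")
                if case_calls is not None:
                    plots.burden_boxplot(
                        {"reference_loo": loo_calls.per_sample_total,
                         "peritumoral": control_calls.per_sample_total,
                         "tumor": case_calls.per_sample_total},
                        outdir / "sem_burden.png",
                    )

        if config.stages.get("shared", True) and case_calls is not None:
            stage = "shared"
            shared = sem.select_shared_sems(
                case_calls, control_calls, annotation,
                fraction=config.shared_fraction,
            )
            shared.probe_table.to_csv(outdir / "shared_sems.tsv", sep="\t", index=False)
            stage_rep = {
                "n_probes": len(shared.probes),
                "genes": shared.genes,
            }
            if regions is not None and shared.genes:
                groups = phenos["tissue_class"]
                pieces = []
                for name, mat in (("reference", reference),
                                  ("peritumoral", controls), ("tumor", cases)):
                    gm = sem.region_group_means(
                        mat, regions, groups.reindex(mat.sample_ids),
                        gene_subset=shared.genes,
                    )
                    pieces.append(gm)
                gene_means = pd.concat(pieces, ignore_index=True).dropna(subset=["group"])
                shared.gene_means = gene_means
                gene_means.to_csv(outdir / "shared_gene_means.tsv", sep="\t", index=False)
                stage_rep["gene_means"] = {
                    f"{r.gene}|{r.region_type}|{r.group}": round(float(riqr), 4)
                    for r, riqr in zip(gene_means.itertuples(), gene_means["mean"])
                    if np.isfinite(riqr)
                }
            if truth is not None:
                stage_rep["planted_shared_genes"] = list(truth.planted_shared_genes)
                stage_rep["recovered_exactly"] = (
                    sorted(shared.genes) == sorted(truth.planted_shared_genes)
                )
            report["stages"]["shared"] = stage_rep

        io.write_report(report, outdir / "report.yaml")
        return report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        io.write_report(report, outdir / "report.yaml")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _pair_map(phenos: pd.DataFrame, cases, controls) -> dict:
    """Case sample -> control sample mapping via shared pair ids."""
    if phenos is None:
        raise ValueError("paired analysis needs a phenotype table with pair ids")
    by_pair = {}
    for sid, row in phenos.iterrows():
        if row["tissue_class"] == "peritumoral":
            by_pair[row["pair_id"]] = sid
    pairs = {}
    for sid in cases.sample_ids:
        pid = phenos.at[sid, "pair_id"]
        if pid not in by_pair:
            raise ValueError(f"case sample {sid} has no paired control ({pid})")
        pairs[sid] = by_pair[pid]
    return pairs
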