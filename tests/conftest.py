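"""Shared fixtures: small toy matrices and the default synthetic cohort."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import semscan as ss
from semscan.containers import BetaMatrix


def make_matrix(values, probe_prefix="cg", sample_prefix="S", detection_p=None):
    """Build a BetaMatrix from a 2-D array with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i + 1:04d}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j + 1:03d}" for j in range(values.shape[1])]
    det = (
        pd.DataFrame(np.asarray(detection_p, dtype=float), index=probes, columns=samples)
        if detection_p is not None
        else None
    )
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples), det)


@pytest.fixture(scope="session")
def small_panel():
    """400-probe panel with genes, regions and flags (seed 7)."""
    spec = ss.ProbePanelSpec(n_probes=400)
    annotation, regions = ss.generate_panel(spec, seed=7)
    return spec, annotation, regions


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 2,000 probes, 114 reference, 20 pairs.

    Returns a dict with annotation, regions, reference matrix, cohort
    matrix, phenotypes (reference + pairs) and the ground-truth table.
    """
    spec = ss.CohortSpec(seed=11)
    panel_spec = ss.ProbePanelSpec()
    annotation, regions = ss.generate_panel(panel_spec, seed=11)
    reference, ref_phenos = ss.generate_reference(annotation, spec.n_reference, spec)
    cohort, phenos, truth = ss.generate_paired_cohort(annotation, reference, spec)
    return {
        "spec": spec,
        "panel_spec": panel_spec,
        "annotation": annotation,
        "regions": regions,
        "reference": reference,
        "cohort": cohort,
        "phenos": pd.concat([ref_phenos, phenos]),
        "cohort_phenos": phenos,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Fences + SEM calls (tumor, peritumoral, reference LOO) on the default cohort."""
    d = default_cohort
    fences = ss.fit_fences(d["reference"], k=3.0, quantile_method="linear")
    ph = d["cohort_phenos"]
    tumor = d["cohort"].subset(samples=ph.index[ph["tissue_class"] == "tumor"])
    peri = d["cohort"].subset(samples=ph.index[ph["tissue_class"] == "peritumoral"])
    return {
        "fences": fences,
        "tumor": ss.call_sems(tumor, fences),
        "peritumoral": ss.call_sems(peri, fences),
        "reference_loo": ss.call_sems_reference_loo(d["reference"], k=3.0),
        "tumor_matrix": tumor,
        "peri_matrix": peri,
    }
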