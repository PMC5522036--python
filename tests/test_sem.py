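"""Fence fitting and SEM calling: worked examples, oracle, properties."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import semscan as ss
from semscan.sem import fit_fences, call_sems, call_sems_reference_loo

from conftest import make_matrix


# ---------------------------------------------------------------- oracles
def brute_force_quartiles(column, method):
    """Independent quartile computation: sorted list + explicit interpolation."""
    x = sorted(v for v in column if not np.isnan(v))
    n = len(x)
    if method == "linear":  # R type 7: h = (n - 1) * q
        def quant(q):
            h = (n - 1) * q
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, n - 1)] - x[lo])
        return quant(0.25), quant(0.75)
    # Tukey hinges: median of each half, halves include the median when n odd
    def median(vals):
        m = len(vals)
        return vals[m // 2] if m % 2 else 0.5 * (vals[m // 2 - 1] + vals[m // 2])
    half = (n + 1) // 2
    return median(x[:half]), median(x[n - half:])


def brute_force_calls(samples, reference, k, method):
    """Per-probe, per-sample fence check, recomputed independently."""
    calls = set()
    for probe in samples.probe_ids:
        ref_col = reference.values.loc[probe].to_numpy()
        if np.sum(~np.isnan(ref_col)) < 8:
            continue
        q1, q3 = brute_force_quartiles(ref_col, method)
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        for sample in samples.sample_ids:
            v = samples.values.at[probe, sample]
            if np.isnan(v):
                continue
            if v > hi:
                calls.add((probe, sample, "hyper"))
            elif v < lo:
                calls.add((probe, sample, "hypo"))
    return calls


# ---------------------------------------------------------------- fences
class TestFitFences:
    def test_worked_example_linear(self):
        ref = make_matrix(np.array([[0.1, 0.2, 0.2, 0.3, 0.9]]))
        f = fit_fences(ref, k=3, quantile_method="linear", min_support=5)
        row = f.table.iloc[0]
        assert row["Q1"] == pytest.approx(0.2)
        assert row["Q3"] == pytest.approx(0.3)
        assert row["IQR"] == pytest.approx(0.1)
        assert row["lower"] == pytest.approx(-0.1)
        assert row["upper"] == pytest.approx(0.6)
        assert row["n_support"] == 5

    def test_constant_column_degenerate(self):
        ref = make_matrix(np.full((1, 10), 0.5))
        f = fit_fences(ref, k=3)
        row = f.table.iloc[0]
        assert row["IQR"] == 0
        assert row["lower"] == row["upper"] == 0.5

    def test_k_zero_gives_quartiles(self):
        rng = np.random.default_rng(0)
        ref = make_matrix(rng.uniform(size=(5, 20)))
        f = fit_fences(ref, k=0)
        assert np.allclose(f.table["lower"], f.table["Q1"])
        assert np.allclose(f.table["upper"], f.table["Q3"])

    @pytest.mark.parametrize("method", ["linear", "tukey"])
    def test_quartiles_match_brute_force(self, method):
        rng = np.random.default_rng(42)
        for n in (8, 9, 10, 13, 114):
            ref = make_matrix(rng.uniform(size=(6, n)))
            f = fit_fences(ref, quantile_method=method)
            for probe in ref.probe_ids:
                q1, q3 = brute_force_quartiles(
                    ref.values.loc[probe].to_numpy(), method
                )
                assert f.table.at[probe, "Q1"] == pytest.approx(q1)
                assert f.table.at[probe, "Q3"] == pytest.approx(q3)

    def test_low_support_probe_excluded(self):
        vals = np.full((2, 10), 0.5)
        vals[1, 3:] = np.nan
        ref = make_matrix(vals)
        f = fit_fences(ref, min_support=8)
        assert list(f.probe_ids) == ["cg0001"]

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fit_fences(make_matrix(np.empty((0, 0))))


# ---------------------------------------------------------------- calling
class TestCallSems:
    def test_strict_fence_boundary(self):
        # dyadic values keep the fences exact in binary floating point:
        # Q1 = 0.25, Q3 = 0.5, k = 1 -> fences (0.0, 0.75)
        ref = make_matrix(np.array([[0.0, 0.25, 0.25, 0.5, 1.0]]))
        fences = fit_fences(ref, k=1, min_support=5)
        row = fences.table.iloc[0]
        assert (row["lower"], row["upper"]) == (0.0, 0.75)
        # 0.8 > upper -> hyper; exactly 0.75 or 0.0 -> strictly not outside
        samples = make_matrix(np.array([[0.8, 0.75, 0.0]]), sample_prefix="C")
        cs = call_sems(samples, fences)
        assert cs.n_calls == 1
        call = cs.calls.iloc[0]
        assert (call["sample_id"], call["direction"]) == ("C001", "hyper")

    def test_missing_never_called(self):
        ref = make_matrix(np.tile([0.4, 0.5, 0.5, 0.6], (1, 3)))
        fences = fit_fences(ref)
        samples = make_matrix(np.array([[np.nan]]))
        assert call_sems(samples, fences).n_calls == 0

    def test_totals_conserved_and_directions_partition(self, default_calls):
        cs = default_calls["tumor"]
        by_sample = cs.calls.groupby("sample_id").size()
        for sid, total in cs.per_sample_total.items():
            assert total == by_sample.get(sid, 0)
        assert set(cs.calls["direction"]).issubset({"hyper", "hypo"})
        assert cs.n_calls == cs.per_sample_total.sum()

    @pytest.mark.parametrize("method", ["linear", "tukey"])
    @pytest.mark.parametrize("k", [1.5, 3.0])
    def test_oracle_equivalence_small_matrices(self, method, k):
        rng = np.random.default_rng(7)
        ref = make_matrix(rng.beta(2, 5, size=(50, 20)), sample_prefix="R")
        samples = make_matrix(rng.beta(2, 5, size=(50, 12)), sample_prefix="C")
        fences = fit_fences(ref, k=k, quantile_method=method)
        got = {
            (r["probe_id"], r["sample_id"], r["direction"])
            for _, r in call_sems(samples, fences).calls.iterrows()
        }
        assert got == brute_force_calls(samples, ref, k, method)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(9)
        ref = make_matrix(rng.beta(2, 8, size=(40, 30)), sample_prefix="R")
        samples = make_matrix(rng.beta(2, 8, size=(40, 10)), sample_prefix="C")
        sets = {}
        for k in (2.0, 3.0, 4.0):
            cs = call_sems(samples, fit_fences(ref, k=k))
            sets[k] = set(map(tuple, cs.calls.to_numpy()))
        assert sets[4.0] <= sets[3.0] <= sets[2.0]


class TestLeaveOneOut:
    def test_single_planted_extreme(self):
        col = np.full((1, 10), 0.5)
        col[0, 0] = 0.51  # tiny jitter so fences are non-degenerate
        vals = np.tile(np.linspace(0.45, 0.55, 10), (1, 1))
        vals[0, 4] = 0.99  # one extreme subject
        ref = make_matrix(vals, sample_prefix="R")
        cs = call_sems_reference_loo(ref, k=3)
        assert cs.n_calls == 1
        assert cs.calls.iloc[0]["sample_id"] == "R005"
        assert cs.calls.iloc[0]["direction"] == "hyper"
        assert cs.reference_mode == "leave_one_out"

    def test_identical_subjects_no_calls(self):
        ref = make_matrix(np.full((5, 12), 0.3))
        assert call_sems_reference_loo(ref).n_calls == 0

    def test_insufficient_subjects_raise(self):
        ref = make_matrix(np.full((3, 8), 0.4))
        with pytest.raises(ValueError, match="leave-one-out"):
            call_sems_reference_loo(ref, min_support=8)

    def test_loo_totals_far_below_tumor(self, default_calls):
        loo_med = default_calls["reference_loo"].per_sample_total.median()
        tum_med = default_calls["tumor"].per_sample_total.median()
        assert loo_med * 10 < tum_med


# ------------------------------------------------------- annotation layers
class TestChromosomeDistribution:
    def test_conservation(self, default_cohort, default_calls):
        cs = default_calls["tumor"]
        dist = ss.sem_chromosome_distribution(cs, default_cohort["annotation"])
        assert dist.to_numpy().sum() == cs.n_calls

    def test_concentrated_and_empty(self):
        ann = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "position": [1, 2], "gene": "",
             "gene_region": "", "snp_overlap": False, "sex_chromosome": False},
            index=["cg0001", "cg0002"],
        )
        calls = pd.DataFrame(
            {"probe_id": ["cg0001", "cg0002"], "sample_id": ["A", "A"],
             "direction": ["hyper", "hypo"]}
        )
        cs = ss.EpimutationCallSet(calls, pd.Series({"A": 2}))
        dist = ss.sem_chromosome_distribution(cs, ann)
        assert dist.loc["chr1", "all"] == 2
        empty = ss.EpimutationCallSet(calls.iloc[:0], pd.Series(dtype=int))
        assert ss.sem_chromosome_distribution(empty, ann).empty


class TestSharedSems:
    @staticmethod
    def _callset(probe_per_sample, n_samples, prefix):
        rows = [
            {"probe_id": p, "sample_id": s, "direction": "hyper"}
            for p, samples in probe_per_sample.items()
            for s in samples
        ]
        calls = pd.DataFrame(rows, columns=["probe_id", "sample_id", "direction"])
        totals = pd.Series(
            0, index=[f"{prefix}{i}" for i in range(n_samples)], dtype=int
        )
        return ss.EpimutationCallSet(calls, totals)

    @staticmethod
    def _ann(probes, gene="GENE1"):
        return pd.DataFrame(
            {"chromosome": "chr1", "position": range(1, len(probes) + 1),
             "gene": gene, "gene_region": "promoter", "snp_overlap": False,
             "sex_chromosome": False},
            index=probes,
        )

    def test_full_prevalence_selected(self):
        case = self._callset({"cgA": [f"T{i}" for i in range(10)]}, 10, "T")
        ctrl = self._callset({}, 10, "P")
        res = ss.select_shared_sems(case, ctrl, self._ann(["cgA"]), fraction=0.9)
        assert res.probes == ["cgA"] and res.genes == ["GENE1"]

    def test_exactly_at_fraction_not_selected(self):
        case = self._callset({"cgA": [f"T{i}" for i in range(9)]}, 10, "T")
        ctrl = self._callset({}, 10, "P")
        res = ss.select_shared_sems(case, ctrl, self._ann(["cgA"]), fraction=0.9)
        assert res.probes == []

    def test_single_control_carrier_excludes(self):
        case = self._callset({"cgA": [f"T{i}" for i in range(10)]}, 10, "T")
        ctrl = self._callset({"cgA": ["P0"]}, 10, "P")
        res = ss.select_shared_sems(case, ctrl, self._ann(["cgA"]), fraction=0.9)
        assert res.probes == []

    def test_empty_case_warns(self):
        case = self._callset({}, 5, "T")
        ctrl = self._callset({}, 5, "P")
        res = ss.select_shared_sems(case, ctrl, self._ann(["cgA"]))
        assert res.probes == [] and res.genes == []


class TestRegionGroupMeans:
    def test_promoter_mean_arithmetic(self):
        m = make_matrix(np.array([[0.1], [0.3]]))
        regions = pd.DataFrame(
            {"region_id": ["prom:G", "prom:G"], "region_type": ["promoter"] * 2,
             "probe_id": ["cg0001", "cg0002"], "gene": ["G", "G"]}
        )
        groups = pd.Series({"S001": "tumor"})
        out = ss.region_group_means(m, regions, groups, region_types=("promoter",))
        assert out.loc[0, "mean"] == pytest.approx(0.2)

    def test_identical_samples_equal_group_mean(self):
        col = np.array([[0.2], [0.6]])
        m = make_matrix(np.hstack([col, col, col]))
        regions = pd.DataFrame(
            {"region_id": ["body:G"] * 2, "region_type": ["gene_body"] * 2,
             "probe_id": ["cg0001", "cg0002"], "gene": ["G", "G"]}
        )
        groups = pd.Series("tumor", index=m.sample_ids)
        out = ss.region_group_means(m, regions, groups, region_types=("gene_body",))
        assert out.loc[0, "mean"] == pytest.approx(0.4)

    def test_planted_gene_reproduces_promoter_body_pattern(self, default_cohort):
        """Tumor promoters gain and gene bodies lose methylation at planted genes."""
        d = default_cohort
        gene = d["truth"].planted_shared_genes[0]
        groups = d["phenos"]["tissue_class"]
        ref_means = ss.region_group_means(
            d["reference"], d["regions"],
            groups.reindex(d["reference"].sample_ids), gene_subset=[gene],
        )
        tum_ids = d["cohort_phenos"].index[d["cohort_phenos"]["tissue_class"] == "tumor"]
        tum_means = ss.region_group_means(
            d["cohort"].subset(samples=tum_ids), d["regions"],
            groups.reindex(tum_ids), gene_subset=[gene],
        )
        def get(df, rtype):
            return df.loc[df["region_type"] == rtype, "mean"].dropna().iloc[0]
        assert get(tum_means, "promoter") > get(ref_means, "promoter")
        assert get(tum_means, "gene_body") < get(ref_means, "gene_body")


# ------------------------------------------------------------- properties
@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.floats(min_value=0, max_value=1, allow_nan=False), min_size=8, max_size=30
    ),
    k_small=st.floats(min_value=0.5, max_value=2.5),
)
def test_fence_width_monotone_in_k(data, k_small):
    """Larger fence multipliers can only widen the interval."""
    ref = make_matrix(np.array([data]))
    narrow = fit_fences(ref, k=k_small).table.iloc[0]
    wide = fit_fences(ref, k=k_small + 1.0).table.iloc[0]
    assert wide["lower"] <= narrow["lower"] + 1e-12
    assert wide["upper"] >= narrow["upper"] - 1e-12
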