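"""Paired tests, p-value adjustment/combination, clustering, MDS."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import semscan as ss
from semscan.containers import BetaMatrix
from semscan.diffmeth import adjust_pvalues, combine_region_pvalues

from conftest import make_matrix


def paired_matrices(diffs, base=0.4):
    """Case/control single-probe matrices with the given per-pair differences
    (difference = control - case)."""
    n = len(diffs)
    case = make_matrix(np.full((1, n), base), sample_prefix="T")
    ctrl = make_matrix(base + np.array([diffs]), sample_prefix="P")
    pairs = {f"T{j + 1:03d}": f"P{j + 1:03d}" for j in range(n)}
    return case, ctrl, pairs


class TestPairedSiteTest:
    def test_matches_textbook_t(self):
        # differences [0.2, 0.0, 0.1, 0.3]: t = mean / (sd / sqrt(4)), df = 3
        d = np.array([0.2, 0.0, 0.1, 0.3])
        case, ctrl, pairs = paired_matrices(d)
        res = ss.paired_site_test(case, ctrl, pairs, method="plain")
        t_oracle = d.mean() / (d.std(ddof=1) / 2.0)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 3)
        row = res.table.iloc[0]
        assert row["statistic"] == pytest.approx(t_oracle)
        assert row["p_value"] == pytest.approx(p_oracle)
        assert row["delta"] == pytest.approx(d.mean())
        assert not row["degenerate"]

    def test_zero_variance_flagged(self):
        case, ctrl, pairs = paired_matrices([0.1, 0.1, 0.1, 0.1])
        res = ss.paired_site_test(case, ctrl, pairs)
        row = res.table.iloc[0]
        assert row["degenerate"]
        assert row["p_value"] == 1.0
        assert np.isnan(row["statistic"])

    def test_identical_case_control_gives_zero_delta(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=(10, 6))
        case = make_matrix(vals, sample_prefix="T")
        ctrl = make_matrix(vals, sample_prefix="P")
        pairs = {f"T{j + 1:03d}": f"P{j + 1:03d}" for j in range(6)}
        res = ss.paired_site_test(case, ctrl, pairs)
        assert np.allclose(res.table["delta"], 0.0)
        assert res.table["degenerate"].all()

    def test_unpaired_sample_named(self):
        case, ctrl, pairs = paired_matrices([0.1, 0.2, 0.3])
        del pairs["T002"]
        with pytest.raises(ValueError, match="T002"):
            ss.paired_site_test(case, ctrl, pairs)

    def test_delta_antisymmetry(self):
        rng = np.random.default_rng(2)
        case = make_matrix(rng.uniform(0.2, 0.8, size=(30, 8)), sample_prefix="T")
        ctrl = make_matrix(rng.uniform(0.2, 0.8, size=(30, 8)), sample_prefix="P")
        fwd_pairs = {f"T{j + 1:03d}": f"P{j + 1:03d}" for j in range(8)}
        rev_pairs = {v: k for k, v in fwd_pairs.items()}
        fwd = ss.paired_site_test(case, ctrl, fwd_pairs)
        rev = ss.paired_site_test(ctrl, case, rev_pairs)
        assert np.allclose(fwd.table["delta"], -rev.table["delta"])
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"])

    def test_moderated_with_zero_prior_weight_equals_plain(self):
        rng = np.random.default_rng(5)
        case = make_matrix(rng.uniform(0.2, 0.8, size=(40, 10)), sample_prefix="T")
        ctrl = make_matrix(rng.uniform(0.2, 0.8, size=(40, 10)), sample_prefix="P")
        pairs = {f"T{j + 1:03d}": f"P{j + 1:03d}" for j in range(10)}
        plain = ss.paired_site_test(case, ctrl, pairs, method="plain")
        mod0 = ss.paired_site_test(case, ctrl, pairs, method="moderated", prior_df=0.0)
        assert np.allclose(plain.table["statistic"], mod0.table["statistic"])
        assert np.allclose(plain.table["p_value"], mod0.table["p_value"])

    def test_moderated_shrinks_extreme_variances(self):
        rng = np.random.default_rng(8)
        vals_c = rng.uniform(0.3, 0.7, size=(200, 6))
        case = make_matrix(vals_c, sample_prefix="T")
        ctrl = make_matrix(vals_c + rng.normal(0, 0.03, size=(200, 6)).clip(-0.2, 0.2),
                           sample_prefix="P")
        pairs = {f"T{j + 1:03d}": f"P{j + 1:03d}" for j in range(6)}
        res = ss.paired_site_test(case, ctrl, pairs, method="moderated")
        assert res.prior_df is None or res.prior_df > 0
        assert res.prior_var is None or res.prior_var > 0


class TestAdjustPvalues:
    def test_bonferroni_single_test_identity(self):
        assert adjust_pvalues([0.01], "bonferroni")[0] == pytest.approx(0.01)

    def test_bh_step_up_hand_example(self):
        # step-up: [.01*3/1, .02*3/2, .03*3/3] -> cummin from the right = [.03,.03,.03]
        out = adjust_pvalues([0.01, 0.02, 0.03], "benjamini_hochberg")
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2], "bonferroni")

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=40))
    def test_inflation_and_bonferroni_dominates_bh(self, p):
        bh = adjust_pvalues(p, "benjamini_hochberg")
        bf = adjust_pvalues(p, "bonferroni")
        assert (bh >= np.asarray(p) - 1e-12).all()
        assert (bf >= bh - 1e-12).all()

    def test_bh_preserves_ranks(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        bh = adjust_pvalues(p, "benjamini_hochberg")
        order = np.argsort(p)
        assert (np.diff(bh[order]) >= -1e-12).all()


def site_result_from_p(pvals, deltas=None):
    n = len(pvals)
    table = pd.DataFrame(
        {
            "mean_control": 0.5, "mean_case": 0.5,
            "delta": deltas if deltas is not None else np.zeros(n),
            "n_pairs": 4, "statistic": 0.0, "p_value": np.asarray(pvals, float),
            "adjusted_p": np.asarray(pvals, float), "degenerate": False,
        },
        index=[f"cg{i + 1:04d}" for i in range(n)],
    )
    return ss.SiteDMResult(table, "plain", "benjamini_hochberg")


def regions_for(probe_ids, region_id="r1", region_type="gene"):
    return pd.DataFrame(
        {"region_id": region_id, "region_type": region_type,
         "probe_id": probe_ids, "gene": ""}
    )


class TestCombineRegionPvalues:
    def test_fisher_closed_form(self):
        res = combine_region_pvalues(
            site_result_from_p([0.5, 0.5]), regions_for(["cg0001", "cg0002"])
        )
        row = res.table.iloc[0]
        assert row["statistic"] == pytest.approx(-2 * 2 * np.log(0.5), rel=1e-3)
        assert row["combined_p"] == pytest.approx(stats.chi2.sf(2.7726, 4), rel=1e-3)
        assert row["n_sites"] == 2

    @pytest.mark.parametrize("method", ["fisher", "stouffer"])
    def test_single_site_identity(self, method):
        res = combine_region_pvalues(
            site_result_from_p([0.037]), regions_for(["cg0001"]), method=method
        )
        assert res.table.iloc[0]["combined_p"] == pytest.approx(0.037, rel=1e-9)

    @pytest.mark.parametrize("method", ["fisher", "stouffer"])
    def test_all_ones_combine_to_one(self, method):
        res = combine_region_pvalues(
            site_result_from_p([1.0, 1.0, 1.0]),
            regions_for(["cg0001", "cg0002", "cg0003"]), method=method,
        )
        assert res.table.iloc[0]["combined_p"] == pytest.approx(1.0)

    def test_zero_p_clamped_not_crashing(self):
        res = combine_region_pvalues(
            site_result_from_p([0.0, 0.5]), regions_for(["cg0001", "cg0002"])
        )
        assert 0 < res.table.iloc[0]["combined_p"] <= 1

    def test_fisher_repeated_p_decreases_with_m(self):
        # for p < 1/e, adding more copies strengthens the combined evidence
        p = 0.2
        prev = 1.0
        for m in (1, 2, 4, 8):
            res = combine_region_pvalues(
                site_result_from_p([p] * m),
                regions_for([f"cg{i + 1:04d}" for i in range(m)]),
            )
            cur = res.table.iloc[0]["combined_p"]
            assert cur < prev + 1e-15
            prev = cur

    def test_region_delta_is_mean_of_member_deltas(self):
        res = combine_region_pvalues(
            site_result_from_p([0.1, 0.2], deltas=[0.3, 0.1]),
            regions_for(["cg0001", "cg0002"]),
        )
        assert res.table.iloc[0]["mean_delta"] == pytest.approx(0.2)


class TestCountSignificant:
    def test_strict_delta_boundary(self):
        res = site_result_from_p([1e-6, 1e-6, 1e-6], deltas=[0.30, 0.31, -0.31])
        counts = ss.count_significant(res, alpha=0.05, delta_threshold=0.30)
        assert counts["n_significant"] == 3
        assert counts["n_significant_large_delta"] == 2

    def test_alpha_zero_nothing_significant(self):
        res = site_result_from_p([1e-6, 0.5])
        assert ss.count_significant(res, alpha=0.0)["n_significant"] == 0


class TestTopKCluster:
    @staticmethod
    def separable(seed=0, n_probes=60, n_per_group=8, shift=0.3):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 0.5, size=(n_probes, 1))
        a = base + rng.normal(0, 0.02, size=(n_probes, n_per_group))
        b = base + shift + rng.normal(0, 0.02, size=(n_probes, n_per_group))
        vals = np.clip(np.hstack([a, b]), 0, 1)
        m = make_matrix(vals)
        labels = pd.Series(
            ["ctrl"] * n_per_group + ["case"] * n_per_group, index=m.sample_ids
        )
        case = m.subset(samples=m.sample_ids[n_per_group:])
        ctrl = m.subset(samples=m.sample_ids[:n_per_group])
        pairs = dict(zip(case.sample_ids, ctrl.sample_ids))
        res = ss.paired_site_test(case, ctrl, pairs)
        return m, res, labels

    def test_separated_groups_no_misclassification(self):
        m, res, labels = self.separable()
        _, _, mis = ss.top_k_cluster(m, res, labels, k=40)
        assert mis == 0

    def test_permuted_labels_near_chance(self):
        m, res, labels = self.separable(seed=3)
        rng = np.random.default_rng(42)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        _, _, mis = ss.top_k_cluster(m, res, perm, k=40)
        # chance-level discordance for balanced random labels is ~n/4 = 4
        assert mis >= 2

    def test_k_larger_than_sites_uses_all(self, caplog):
        m, res, labels = self.separable()
        _, _, mis = ss.top_k_cluster(m, res, labels, k=10_000)
        assert mis == 0


class TestMds:
    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        coords = ss.mds_embed(pts, dims=2)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(
            coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=-1
        )
        assert np.allclose(d0, d1, atol=1e-8)

    def test_duplicate_samples_coincide(self):
        vals = np.random.default_rng(1).uniform(size=(20, 5))
        vals[:, 4] = vals[:, 0]  # duplicate sample
        m = make_matrix(vals)
        coords = ss.mds_embed(m)
        assert np.allclose(coords.iloc[0], coords.iloc[4], atol=1e-8)

    def test_group_shift_separates_on_first_axis(self):
        m, _, labels = TestTopKCluster.separable(seed=5, shift=0.35)
        coords = ss.mds_embed(m)
        a = coords.loc[labels == "ctrl", "dim1"]
        b = coords.loc[labels == "case", "dim1"]
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_degenerate_input_zeros(self):
        m = make_matrix(np.full((10, 4), 0.5))
        coords = ss.mds_embed(m)
        assert np.allclose(coords.to_numpy(), 0.0)
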