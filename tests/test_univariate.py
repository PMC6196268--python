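"""Differential expression, p-value adjustment, group tests, bi-clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nksig.io import ExpressionMatrix, SampleMetadata
from nksig.univariate import (adjust_pvalues, differential_expression,
                              group_mean_test, hierarchical_bicluster)


def _two_group(values, n_per_group):
    values = np.asarray(values, dtype=float)
    samples = [f"b{i}" for i in range(n_per_group)] + \
              [f"d{i}" for i in range(n_per_group)]
    m = ExpressionMatrix(pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])],
        columns=samples), "log2")
    md = SampleMetadata(pd.DataFrame(
        {"group": ["bright"] * n_per_group + ["dim"] * n_per_group},
        index=pd.Index(samples, name="sample_id")))
    return m, md


class TestAdjustPvalues:
    def test_bh_hand_step_up(self):
        # sorted p * m / rank: .04, .04, .04, .04 after the step-up pass
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        np.testing.assert_allclose(out, [0.04] * 4)

    def test_single_p_unchanged_under_bh(self):
        np.testing.assert_allclose(adjust_pvalues([0.03], "bh"), [0.03])

    def test_bonferroni_multiplies_by_m(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.5, 0.9, 0.2], "bonferroni")[0], 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])

    def test_bh_never_decreases_and_dominates_bonferroni(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        bh = adjust_pvalues(p, "bh")
        bon = adjust_pvalues(p, "bonferroni")
        assert (bh >= p - 1e-15).all()
        # Bonferroni-significant set is a subset of the BH-significant set
        assert set(np.flatnonzero(bon <= 0.05)) <= set(np.flatnonzero(bh <= 0.05))


class TestDifferentialExpression:
    def test_identical_groups_all_unchanged(self):
        block = np.tile(np.linspace(2, 6, 5)[:, None], (1, 4))
        values = np.concatenate([block, block], axis=1)
        m, md = _two_group(values, 4)
        res = differential_expression(m, md, apply_detection_filter=False)
        assert all(r.status == "unchanged" and r.delta == 0 for r in res)

    def test_planted_shift_recovered_as_induced(self):
        rng = np.random.default_rng(3)
        d, n = 40, 10
        base = rng.uniform(3, 7, size=d)
        bright = base[:, None] + rng.normal(0, 0.3, (d, n))
        dim = base[:, None] + rng.normal(0, 0.3, (d, n))
        dim[:20] += 1.5
        m, md = _two_group(np.concatenate([bright, dim], axis=1), n)
        res = {r.feature: r for r in differential_expression(m, md)}
        for i in range(20):
            assert res[f"f{i}"].status == "induced"
        assert all(res[f"f{i}"].status == "unchanged" for i in range(20, 40))

    def test_two_fold_rule_blocks_small_deltas(self):
        # delta=1.2 with tiny noise -> induced; delta=0.8 -> unchanged
        n = 6
        rng = np.random.default_rng(4)
        base = np.full(n, 5.0)
        rows = []
        for delta in (1.2, 0.8):
            bright = base + rng.normal(0, 0.01, n)
            dim = base + delta + rng.normal(0, 0.01, n)
            rows.append(np.concatenate([bright, dim]))
        m, md = _two_group(np.array(rows), n)
        res = {r.feature: r for r in
               differential_expression(m, md, apply_detection_filter=False)}
        assert res["f0"].status == "induced" and res["f0"].p_adj < 0.01
        assert res["f1"].status == "unchanged" and res["f1"].p_adj < 0.01

    def test_label_swap_antisymmetry(self, small_normalized):
        norm, md, _ = small_normalized
        res_fwd = differential_expression(norm, md)
        swapped = md.table.copy()
        swapped["group"] = swapped["group"].map(
            {"bright": "dim", "dim": "bright"})
        md_swapped = SampleMetadata(swapped)
        res_rev = {r.feature: r for r in
                   differential_expression(norm, md_swapped)}
        flip = {"induced": "repressed", "repressed": "induced",
                "unchanged": "unchanged"}
        for r in res_fwd:
            assert res_rev[r.feature].delta == pytest.approx(-r.delta)
            assert res_rev[r.feature].status == flip[r.status]

    def test_null_type_i_calibration(self, null_dataset):
        """Under the global null the raw-p positive rate sits at the nominal
        level, within binomial error."""
        norm, md, _ = null_dataset
        res = differential_expression(norm, md)
        frac = np.mean([r.p_raw <= 0.05 for r in res])
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) <= 3 * se
        assert not any(r.status != "unchanged" for r in res)

    def test_small_group_and_bad_alpha_rejected(self):
        m, md = _two_group(np.ones((2, 4)), 2)
        with pytest.raises(ValueError, match="alpha"):
            differential_expression(m, md, alpha=1.5)
        m1, md1 = _two_group(np.ones((2, 2)), 1)
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression(m1, md1)


class TestGroupMeanTest:
    def test_mann_whitney_exact_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        _, p = group_mean_test(a, a.copy(), kind="mann_whitney")
        assert p == 1.0

    def test_mann_whitney_exact_matches_enumeration_with_ties(self):
        from scipy.stats import rankdata
        a, b = np.array([1.0, 2.0, 2.0]), np.array([2.0, 4.0, 5.0])
        _, p = group_mean_test(a, b, kind="mann_whitney")
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        center = 4.5
        obs = abs(ranks[:3].sum() - 6 - center)
        hits = sum(abs(ranks[list(c)].sum() - 6 - center) >= obs - 1e-12
                   for c in itertools.combinations(range(6), 3))
        assert p == pytest.approx(hits / 20)

    def test_shifted_samples_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(3, 1, 10)
        for kind in ("welch_t", "mann_whitney"):
            _, p = group_mean_test(a, b, kind=kind)
            assert p < 0.05

    def test_anova_requires_three_groups(self):
        with pytest.raises(ValueError, match="three"):
            group_mean_test([1.0, 2.0], [2.0, 3.0], kind="anova_bonferroni")

    def test_anova_identical_groups_post_p_clipped_to_one(self):
        g = [5.0, 5.1, 4.9]
        _, _, post = group_mean_test(g, list(g), list(g),
                                     kind="anova_bonferroni")
        assert all(p == 1.0 for p in post.values())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_mean_test([], [1.0], kind="welch_t")


class TestBicluster:
    def _matrix(self, values, samples=None):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(pd.DataFrame(
            values, index=[f"f{i}" for i in range(values.shape[0])],
            columns=samples or [f"s{j}" for j in range(values.shape[1])]),
            "log2")

    def test_identical_samples_merge_at_height_zero(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=5)
        m = self._matrix(np.column_stack([col, col, rng.normal(size=5)]))
        _, samp_tree = hierarchical_bicluster(m, metric="euclidean")
        first = samp_tree.linkage_matrix[0]
        assert first[2] == 0.0
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_planted_two_group_partition_is_top_split(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 0.1, size=(6, 4))
        base[:, 2:] += 5.0
        m = self._matrix(base, samples=["a1", "a2", "z1", "z2"])
        _, samp_tree = hierarchical_bicluster(m, metric="euclidean")
        cut = samp_tree.cut(2)
        assert cut["a1"] == cut["a2"] != cut["z1"]
        assert cut["z1"] == cut["z2"]
        assert sorted(samp_tree.leaf_order) == ["a1", "a2", "z1", "z2"]

    def test_leaf_count_and_newick(self):
        rng = np.random.default_rng(8)
        m = self._matrix(rng.normal(size=(5, 4)))
        feat_tree, samp_tree = hierarchical_bicluster(m, metric="euclidean")
        assert len(feat_tree.leaf_order) == 5
        assert len(samp_tree.leaf_order) == 4
        newick = feat_tree.to_newick()
        assert newick.endswith(";") and newick.count(",") == 4

    def test_constant_matrix_correlation_advises_euclidean(self):
        m = self._matrix(np.ones((3, 4)))
        with pytest.raises(ValueError, match="euclidean"):
            hierarchical_bicluster(m, metric="correlation")
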