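"""Normalization, volcano/Venn contrasts, PCA and quartile assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bniscreen.containers import AbundanceMatrix
from bniscreen.preprocess import (abundance_balance, aggregate_by_class,
                                  normalize_gcms, pca,
                                  quartiles_by_inhibition, venn_membership,
                                  volcano)


def _make_am(vals, origins=None, weights=None):
    genos = [f"g{i}" for i in range(vals.shape[0])]
    mets = [f"m{i}" for i in range(vals.shape[1])]
    n = len(genos)
    gmeta = pd.DataFrame({
        "origin": origins or (["A"] * (n // 2) + ["B"] * (n - n // 2)),
        "root_dry_weight": weights if weights is not None else np.ones(n),
    }, index=genos)
    mmeta = pd.DataFrame({"chemical_class": ["c"] * len(mets)}, index=mets)
    return AbundanceMatrix(pd.DataFrame(vals, index=genos, columns=mets), gmeta, mmeta)


class TestNormalizeGcms:
    def test_zero_maps_to_zero_and_log10(self):
        a = _make_am(np.array([[0.0, 99.0], [0.0, 198.0]]), weights=np.array([1.0, 2.0]))
        out = normalize_gcms(a).values
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(2.0)  # log10(99/1 + 1)
        assert out.iloc[1, 1] == pytest.approx(2.0)  # log10(198/2 + 1)

    def test_heavier_roots_lower_values(self):
        vals = np.random.default_rng(0).uniform(1, 50, (4, 3))
        a1 = _make_am(vals, weights=np.ones(4))
        a2 = _make_am(vals, weights=2 * np.ones(4))
        assert (normalize_gcms(a2).values.values < normalize_gcms(a1).values.values).all()

    def test_missing_weight_errors(self):
        a = _make_am(np.ones((4, 2)))
        a.genotype_meta.loc["g1", "root_dry_weight"] = np.nan
        with pytest.raises(ValueError, match="g1"):
            normalize_gcms(a)


class TestAbundanceBalance:
    def test_row_sums_become_grand_mean(self, tiny_abundance):
        before = tiny_abundance.values.sum(axis=1)
        out = abundance_balance(tiny_abundance)
        after = out.values.sum(axis=1)
        assert np.allclose(after, before.mean())
        # total intensity conserved
        assert out.values.values.sum() == pytest.approx(
            tiny_abundance.values.values.sum(), rel=1e-9)

    def test_equal_row_sums_fixed_point(self):
        vals = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        a = _make_am(vals)
        pd.testing.assert_frame_equal(abundance_balance(a).values, a.values)

    def test_all_zero_row_rejected(self):
        a = _make_am(np.array([[1.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="g1"):
            abundance_balance(a)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(float, (5, 4), elements=st.floats(0.1, 1e4)))
    def test_conservation_property(self, vals):
        a = _make_am(vals)
        out = abundance_balance(a)
        assert out.values.values.sum() == pytest.approx(vals.sum(), rel=1e-9)


class TestVolcano:
    def test_identical_groups_ns(self):
        vals = np.tile(np.array([[1.0, 5.0]]), (6, 1))
        v = volcano(_make_am(vals))
        assert (v.table["category"] == "ns").all()
        assert (v.table["signed_fold_change"] == 1.0).all()

    def test_threshold_logic_up_A(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 2, size=(12, 1))
        vals = base.copy()
        vals[:6] *= 8.0  # A group 8x higher
        v = volcano(_make_am(vals))
        assert v.table["category"].iloc[0] == "up_A"
        assert v.table["signed_fold_change"].iloc[0] >= 2.0

    def test_scale_invariance(self, tiny_abundance):
        v1 = volcano(tiny_abundance)
        scaled = tiny_abundance.copy_with(tiny_abundance.values * 37.0)
        v2 = volcano(scaled)
        assert (v1.table["category"] == v2.table["category"]).all()
        assert np.allclose(v1.table["p_value"], v2.table["p_value"])


class TestVenn:
    def test_memberships(self):
        vals = np.ones((6, 4))
        vals[:, 1] = 0.0                      # absent
        vals[3:, 2] = 0.0                     # A_only
        vals[:3, 3] = 0.0                     # B_only
        m = venn_membership(_make_am(vals))
        assert list(m) == ["shared", "absent", "A_only", "B_only"]

    def test_presence_fraction_bounds(self, tiny_abundance):
        with pytest.raises(ValueError):
            venn_membership(tiny_abundance, presence_fraction=0.0)


class TestPCA:
    def test_rank_one_matrix(self):
        u = np.arange(1, 7, dtype=float)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        res = pca(_make_am(u @ v))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_reproduce_scores(self, tiny_abundance):
        res = pca(tiny_abundance)
        X = tiny_abundance.values.to_numpy()
        Xc = X - X.mean(axis=0)
        assert np.allclose(Xc @ res.loadings.to_numpy(), res.scores.to_numpy(), atol=1e-8)
        assert res.variance_explained.sum() <= 1.0 + 1e-12
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_matches_bruteforce_eigenvalues(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 10, size=(8, 8))
        res = pca(_make_am(vals, origins=["A"] * 4 + ["B"] * 4))
        cov = np.cov(vals, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.variance_explained, (eig / eig.sum())[: len(res.variance_explained)],
                           atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(_make_am(np.ones((4, 3))))


class TestAggregateAndQuartiles:
    def test_class_rows_sum_to_one(self, tiny_abundance):
        out = aggregate_by_class(tiny_abundance)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_class_means_match_groupby(self, tiny_abundance):
        out = aggregate_by_class(tiny_abundance)
        manual = tiny_abundance.values[["m0", "m1"]].mean(axis=1)
        scaled = manual / manual.sum()
        assert np.allclose(out.loc["x"], scaled)

    def test_quartile_sizes_44(self, small_study):
        q = quartiles_by_inhibition(small_study.inhibition)
        assert sorted(q.labels.value_counts()) == [11, 11, 11, 11]
        top = q.mean_inhibition.idxmax()
        assert q.labels[top] == "Q1"

    def test_tie_rule_by_id(self, simple_inhibition):
        reps = simple_inhibition.replicates.copy()
        reps["aoi"] = 10.0
        from bniscreen.containers import InhibitionMatrix
        q = quartiles_by_inhibition(InhibitionMatrix(reps))
        genos = sorted(reps["genotype"].unique())
        assert q.labels[genos[0]] == "Q1" and q.labels[genos[-1]] == "Q4"
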