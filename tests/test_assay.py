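"""AOI% identities, EC50 fitting, rank tests and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bniscreen.assay import (aoi_single_timepoint, aoi_slope_based,
                             cluster_inhibition, compare_strains, dunn_posthoc,
                             fit_ec50, nitrite_from_absorbance)
from bniscreen.containers import DoseResponseSeries, InhibitionMatrix
from bniscreen.synthetic_data import simulate_doseresponse


class TestNitriteCalibration:
    def test_linear_recovery(self):
        standards = [(0.1, 10.0), (0.2, 20.0), (0.4, 40.0)]
        out = nitrite_from_absorbance([0.3], standards)
        assert out[0] == pytest.approx(30.0)

    def test_below_blank_clipped_with_warning(self):
        standards = [(0.1, 0.0), (0.2, 10.0), (0.3, 20.0)]
        with pytest.warns(UserWarning):
            out = nitrite_from_absorbance([0.0], standards)
        assert out[0] == 0.0

    def test_degenerate_standards(self):
        with pytest.raises(ValueError):
            nitrite_from_absorbance([0.1], [(0.2, 1.0), (0.2, 2.0), (0.2, 3.0)])


class TestAoi:
    def test_identities(self):
        assert aoi_single_timepoint([5, 5, 5], [5, 5, 5]) == 0.0
        assert aoi_single_timepoint([0, 0], [4, 6]) == 100.0
        assert aoi_single_timepoint([7.5], [5.0]) == pytest.approx(-50.0)

    def test_unit_rescaling_invariance(self):
        t, c = np.array([1.0, 2.0]), np.array([3.0, 5.0])
        assert aoi_single_timepoint(t, c) == pytest.approx(
            aoi_single_timepoint(t / 1000.0, c / 1000.0))

    def test_control_zero_rejected(self):
        with pytest.raises(ValueError):
            aoi_single_timepoint([1.0], [0.0])

    def test_slope_based_matches_rate_ratio(self):
        s = simulate_doseresponse(ec50=1.0, hill=1.0, noise_cv=0.0, seed=0)
        aoi = aoi_slope_based(s)
        # sigmoidal kinetics: AOI%(c) = 100 * c / (c + ec50)
        expected = 100.0 * aoi["concentration"] / (aoi["concentration"] + 1.0)
        assert np.allclose(aoi["aoi"], expected, atol=1e-8)

    def test_slope_needs_three_timepoints(self):
        df = pd.DataFrame({
            "concentration": [0, 0, 0, 0, 1, 1, 1, 1],
            "timepoint": [0, 0, 1, 1, 0, 0, 1, 1],
            "replicate": [1, 2, 1, 2, 1, 2, 1, 2],
            "nitrite": [0, 0, 1, 1.1, 0, 0, 0.5, 0.6]})
        s = DoseResponseSeries("x", "y", df)
        with pytest.raises(ValueError):
            aoi_slope_based(s)


class TestEc50:
    def test_noise_free_recovery(self):
        for h in (0.8, 1.0, 2.0):
            s = simulate_doseresponse(ec50=1.0, hill=h, noise_cv=0.0, seed=0)
            fit = fit_ec50(aoi_slope_based(s)[["concentration", "aoi"]].to_numpy())
            assert fit.converged
            assert fit.ec50 == pytest.approx(1.0, rel=0.01)

    def test_flat_response_not_estimable(self):
        pairs = [(0.1, 0.0), (1.0, 0.0), (10.0, 0.0), (100.0, 0.0)]
        with pytest.raises(ValueError, match="not estimable"):
            fit_ec50(pairs)

    def test_interpolation_fallback_brackets(self):
        # non-sigmoidal shape: force fallback by a degenerate zig-zag that
        # still brackets 50% between 0.5 and 2
        pairs = [(0.1, 10.0), (0.5, 40.0), (2.0, 60.0), (10.0, 55.0)]
        fit = fit_ec50(pairs)
        assert 0.1 < fit.ec50 < 10.0


def _wilcoxon_exact_p(x, y):
    """Exact two-sided rank-sum p by full enumeration (no ties assumed)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    all_w = [sum(c) for c in itertools.combinations(ranks, n1)]
    all_w = np.array(all_w)
    mu = all_w.mean()
    p = np.mean(np.abs(all_w - mu) >= abs(w_obs - mu) - 1e-9)
    return w_obs, p


def _kw_h_oracle(groups):
    """Kruskal-Wallis H with tie correction, from the textbook formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos: pos + len(g)]
        pos += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def _to_inh(groups, labels):
    rows = []
    for lab, vals in zip(labels, groups):
        for i, v in enumerate(vals):
            rows.append((f"g{lab}{i}", lab, 1, v))
    return InhibitionMatrix(pd.DataFrame(rows, columns=["genotype", "strain", "replicate", "aoi"]))


class TestRankStatOracles:
    def test_wilcoxon_complete_separation_exact(self):
        """n1=n2=5 with complete separation: W = 40, p = 0.0079."""
        inh = _to_inh([[10, 11, 12, 13, 14], [1, 2, 3, 4, 5]], ["a", "b"])
        res = compare_strains(inh, grouping="strain")
        assert res.statistic == 40.0
        # 2-sided exact: 2 of the C(10,5)=252 assignments are this extreme
        assert res.p_value == pytest.approx(2 / 252, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_wilcoxon_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        w_ref, p_ref = _wilcoxon_exact_p(x, y)
        res = compare_strains(_to_inh([x, y], ["a", "b"]), grouping="strain")
        assert res.statistic == pytest.approx(w_ref)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_kw_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
        res = compare_strains(_to_inh(groups, ["a", "b", "c"]), grouping="strain")
        assert res.statistic == pytest.approx(_kw_h_oracle(groups), abs=1e-10)

    def test_identical_groups_h_zero(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        inh = _to_inh([vals, vals, vals], ["a", "b", "c"])
        res = compare_strains(inh, grouping="strain")
        assert res.statistic == 0.0
        # all share a letter
        assert len(set(res.group_letters.values())) == 1

    def test_dunn_bonferroni_geq_raw(self):
        rng = np.random.default_rng(2)
        groups = {c: rng.normal(loc=i, size=6) for i, c in enumerate("abc")}
        tab = dunn_posthoc(groups)
        assert (tab["p_adj"] >= tab["p_raw"] - 1e-12).all()

    def test_letters_consistent_with_pairwise(self, small_study):
        res = compare_strains(small_study.inhibition, grouping="strain")
        letters = res.group_letters
        for _, row in res.pairwise.iterrows():
            shared = set(letters[row["group1"]]) & set(letters[row["group2"]])
            if row["p_adj"] < 0.05:
                assert not shared
            else:
                assert shared


class TestClustering:
    def test_identical_rows_merge_at_zero(self, simple_inhibition):
        reps = simple_inhibition.replicates.copy()
        dup = reps[reps["genotype"] == "g0"].assign(genotype="g0b")
        inh = InhibitionMatrix(pd.concat([reps, dup], ignore_index=True))
        res = cluster_inhibition(inh)
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_monotone_heights_and_stable_order(self, simple_inhibition):
        r1 = cluster_inhibition(simple_inhibition)
        r2 = cluster_inhibition(simple_inhibition)
        assert (np.diff(r1.row_linkage[:, 2]) >= -1e-12).all()
        assert r1.row_order == r2.row_order and r1.col_order == r2.col_order

    def test_missing_values_require_impute_flag(self, simple_inhibition):
        reps = simple_inhibition.replicates
        reps = reps[~((reps["genotype"] == "g0") & (reps["strain"] == "NF"))]
        inh = InhibitionMatrix(reps.reset_index(drop=True))
        with pytest.raises(ValueError):
            cluster_inhibition(inh)
        cluster_inhibition(inh, impute_missing=True)
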