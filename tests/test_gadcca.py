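"""CCA fitness backends, GA selection and stability checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bniscreen.gadcca import (DCCAConfig, GAConfig, LinearCCAFitness,
                              dcca_fitness, ga_select, stability_check)


def _frame(n, p, seed=0, prefix="m"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)),
                        index=[f"g{i}" for i in range(n)],
                        columns=[f"{prefix}{i}" for i in range(p)])


class TestLinearBackend:
    def test_equals_multiple_correlation(self):
        X = _frame(30, 5, seed=1)
        rng = np.random.default_rng(2)
        y = pd.Series(X["m0"].values + rng.normal(0, 0.5, 30), index=X.index)
        fit = LinearCCAFitness(X, y)
        r = fit((0, 1, 2))
        # oracle: sqrt(R^2) from ordinary least squares
        import numpy.linalg as la
        A = np.column_stack([X[["m0", "m1", "m2"]].to_numpy(), np.ones(30)])
        coef, *_ = la.lstsq(A, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - A @ coef
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r == pytest.approx(np.sqrt(r2), abs=1e-10)

    def test_constant_response_rejected(self):
        X = _frame(12, 4)
        with pytest.raises(ValueError):
            LinearCCAFitness(X, pd.Series(5.0, index=X.index))


class TestDccaFitness:
    def test_linear_activation_matches_linear_cca(self):
        X = _frame(200, 3, seed=42)
        rng = np.random.default_rng(43)
        y = pd.Series(X["m0"].values + 0.5 * X["m1"].values + rng.normal(0, 1, 200),
                      index=X.index)
        ref = LinearCCAFitness(X, y)((0, 1, 2))
        got = dcca_fitness(["m0", "m1", "m2"], X, y,
                           DCCAConfig(activation="linear", epochs=300, seed=0))
        assert got == pytest.approx(ref, abs=0.02)

    def test_recovers_linear_signal(self):
        X = _frame(100, 3, seed=7)
        y = pd.Series(2.0 * X["m1"].values, index=X.index)
        f = dcca_fitness(["m0", "m1", "m2"], X, y, DCCAConfig(epochs=300, seed=0))
        assert f >= 0.99

    def test_null_below_permutation_quantile(self):
        X = _frame(60, 3, seed=8)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=60), index=X.index)
        cfg = DCCAConfig(epochs=150, seed=0)
        f_obs = dcca_fitness(["m0", "m1", "m2"], X, y, cfg)
        null = []
        for k in range(20):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=X.index)
            null.append(dcca_fitness(["m0", "m1", "m2"], X, yp, cfg))
        # observed null fitness should not stand out from the permutation null
        assert f_obs <= np.quantile(null, 0.95) + 0.05

    def test_determinism_and_constant_column(self):
        X = _frame(40, 3, seed=10)
        y = pd.Series(X["m0"].values, index=X.index)
        cfg = DCCAConfig(epochs=100, seed=3)
        assert dcca_fitness(["m0", "m1", "m2"], X, y, cfg) == dcca_fitness(
            ["m0", "m1", "m2"], X, y, cfg)
        X2 = X.copy()
        X2["m2"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            f = dcca_fitness(["m0", "m1", "m2"], X2, y, cfg)
        assert 0.0 <= f <= 1.0


class TestGaSelect:
    def test_counting_identity_and_determinism(self):
        X = _frame(30, 15, seed=3)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=30), index=X.index)
        ga = GAConfig(repetitions=12, generations=5, population=10, seed=5)
        t1 = ga_select(X, y, ga)
        t2 = ga_select(X, y, ga)
        assert t1.table["f"].sum() == 3 * 12
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_single_signal_attains_max_frequency(self):
        X = _frame(40, 21, seed=6)
        y = pd.Series(3.0 * X["m7"].values + np.random.default_rng(7).normal(0, 0.5, 40),
                      index=X.index)
        ga = GAConfig(repetitions=50, generations=10, population=20, seed=8)
        tbl = ga_select(X, y, ga)
        assert tbl.table["f"].idxmax() == "m7"
        assert tbl.table.loc["m7", "f"] == tbl.table["f"].max()

    def test_exhaustive_oracle_small(self):
        """GA's best triplet fitness matches exhaustive search on 10 features."""
        X = _frame(25, 10, seed=11)
        rng = np.random.default_rng(12)
        y = pd.Series(X["m2"].values - X["m5"].values + rng.normal(0, 0.3, 25),
                      index=X.index)
        fit = LinearCCAFitness(X, y)
        best_exh = max(fit(c) for c in itertools.combinations(range(10), 3))
        tbl = ga_select(X, y, GAConfig(repetitions=3, generations=15,
                                       population=20, seed=13))
        best_ga = max(f for _, f in tbl.best_triplets)
        assert best_ga == pytest.approx(best_exh, abs=1e-12)

    def test_validation(self):
        X = _frame(20, 3, seed=1)
        y = pd.Series(np.arange(20.0), index=X.index)
        with pytest.raises(ValueError):
            ga_select(X, y, GAConfig())  # features == subset_size
        with pytest.raises(ValueError):
            GAConfig(repetitions=0)


class TestStability:
    def test_planted_signal_stable_across_splits(self):
        X = _frame(44, 15, seed=20)
        y = pd.Series(4.0 * X["m3"].values, index=X.index)
        rep = stability_check(X, y, GAConfig(repetitions=8, generations=8,
                                             population=12, seed=21), repeats=5)
        assert all(tops[0] == "m3" for tops in rep.top_sets)
        assert rep.rank_correlations.shape == (5, 5)

    def test_single_repeat_flagged(self):
        X = _frame(20, 8, seed=22)
        y = pd.Series(X["m1"].values, index=X.index)
        rep = stability_check(X, y, GAConfig(repetitions=3, generations=3,
                                             population=8, seed=23), repeats=1)
        assert rep.degenerate and np.isnan(rep.top_k_overlap)

    def test_degenerate_split_rejected(self):
        X = _frame(10, 8, seed=24)
        y = pd.Series(X["m1"].values, index=X.index)
        with pytest.raises(ValueError, match="degenerate"):
            stability_check(X, y, GAConfig(repetitions=2, population=6), repeats=2)
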