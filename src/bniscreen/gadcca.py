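"""Genetic-algorithm metabolite-triplet selection under a CCA fitness.

The selector searches for *combinations* of metabolites (triplets by
default) whose joint canonical correlation with a strain's inhibition
activity is maximal.  Each GA individual is a set of ``subset_size``
distinct metabolites; fitness is the canonical correlation between the
subset's (standardized) abundances and the (standardized) AOI vector,
computed either by

* ``linear-cca`` — the closed-form canonical correlation of a
  three-column block against a single response (equals the multiple
  correlation coefficient), cheap enough for hundreds of GA repetitions; or
* ``dcca`` — a small deep canonical correlation model: two fully-connected
  encoders (one per view) trained jointly to maximize the regularized
  correlation of their scalar latent outputs.  Implemented in pure numpy
  (manual backprop + Adam); nets are tiny and samples few, so this is fast
  enough for spot checks.

Across many independent GA repetitions the members of each repetition's
best triplet are counted; metabolites with high occurrence frequency are
the reproducibly informative ones.  A subsampling stability check (80/20
splits) verifies that the frequency ranking is not an artifact of the
particular genotype set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .synthetic_data import standardized_log_abundance

__all__ = [
    "DCCAConfig",
    "GAConfig",
    "TripletFrequencyTable",
    "StabilityReport",
    "LinearCCAFitness",
    "dcca_fitness",
    "ga_select",
    "stability_check",
]


@dataclass(frozen=True)
class DCCAConfig:
    hidden_layers: tuple[int, ...] = (16, 16)
    activation: str = "tanh"          # tanh | linear | relu
    latent_dim: int = 1
    epochs: int = 300
    learning_rate: float = 1e-2
    covariance_regularizer: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim != 1:
            raise ValueError("only latent_dim=1 is supported")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class GAConfig:
    subset_size: int = 3
    population: int = 40
    generations: int = 30
    mutation_rate: float = 0.10
    tournament_size: int = 3
    elitism: int = 2
    repetitions: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


# ---------------------------------------------------------------------------
# Fitness backends


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _as_feature_frame(a) -> pd.DataFrame:
    """Accept an AbundanceMatrix (-> standardized log10) or plain DataFrame."""
    if isinstance(a, AbundanceMatrix):
        return standardized_log_abundance(a)
    return a


class LinearCCAFitness:
    """Closed-form canonical correlation of a column subset vs one response.

    For a single response the first canonical correlation equals the
    multiple correlation sqrt(R^2) of the least-squares regression of y on
    the subset.  Gram matrices are precomputed once so each subset costs a
    tiny k x k solve.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series):
        y = y.loc[X.index]
        if y.std(ddof=0) == 0:
            raise ValueError("constant response: canonical correlation undefined")
        self.columns = list(X.columns)
        Xs = _standardize_columns(X.to_numpy(dtype=float))
        ys = (y.to_numpy(dtype=float) - y.mean()) / y.std(ddof=0)
        self._XtX = Xs.T @ Xs
        self._Xty = Xs.T @ ys
        self._yty = ys @ ys

    def __call__(self, idx: tuple[int, ...]) -> float:
        ix = list(idx)
        G = self._XtX[np.ix_(ix, ix)]
        b = self._Xty[ix]
        try:
            sol = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(G, b, rcond=None)[0]
        r2 = float(b @ sol) / self._yty
        return float(np.sqrt(np.clip(r2, 0.0, 1.0)))


class _MLP:
    """Tiny fully-connected net with manual backprop (scalar output)."""

    def __init__(self, sizes: list[int], activation: str, rng: np.random.Generator):
        self.activation = activation
        self.W = []
        self.b = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            self.W.append(rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))

    def _act(self, z):
        if self.activation == "tanh":
            return np.tanh(z)
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        return z

    def _act_grad(self, z, a):
        if self.activation == "tanh":
            return 1.0 - a**2
        if self.activation == "relu":
            return (z > 0).astype(float)
        return np.ones_like(z)

    def forward(self, X):
        self._zs, self._as = [], [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            self._zs.append(z)
            h = z if i == len(self.W) - 1 else self._act(z)  # linear output layer
            self._as.append(h)
        return h[:, 0]

    def backward(self, dout):
        """dout: gradient wrt scalar output per sample, shape (n,)."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.W)
        delta = dout[:, None]
        for i in range(len(self.W) - 1, -1, -1):
            grads_W[i] = self._as[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * self._act_grad(self._zs[i - 1], self._as[i])
        return grads_W, grads_b

    def params(self):
        return self.W + self.b

    def grads_list(self, gW, gb):
        return gW + gb


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p += self.lr * mhat / (np.sqrt(vhat) + eps)  # ascent


def _corr_and_grads(fa: np.ndarray, fb: np.ndarray, reg: float):
    """Squared correlation of two scalar outputs and its per-sample grads."""
    n = len(fa)
    ac = fa - fa.mean()
    bc = fb - fb.mean()
    sab = ac @ bc / n
    saa = ac @ ac / n + reg
    sbb = bc @ bc / n + reg
    rho2 = sab**2 / (saa * sbb)
    # d rho2 / d fa_i ; centering handled because sum(bc) = sum(ac) = 0
    dfa = (2 * sab / (saa * sbb)) * bc / n - (sab**2 / (saa**2 * sbb)) * 2 * ac / n
    dfb = (2 * sab / (saa * sbb)) * ac / n - (sab**2 / (saa * sbb**2)) * 2 * bc / n
    rho = sab / np.sqrt(saa * sbb)
    return rho, rho2, dfa, dfb


def dcca_fitness(triplet, a, y: pd.Series, cfg: DCCAConfig = DCCAConfig()) -> float:
    """Deep-CCA fitness of one metabolite subset against one AOI vector.

    Two encoders (subset -> latent scalar, y -> latent scalar) are trained
    jointly by full-batch Adam to maximize the regularized squared
    correlation of their outputs; the returned fitness is the absolute
    final correlation on the training data, in [0, 1].  Fully deterministic
    given ``cfg.seed``.
    """
    X_df = _as_feature_frame(a)
    y = y.loc[X_df.index]
    if y.std(ddof=0) == 0:
        raise ValueError("constant response: canonical correlation undefined")
    cols = [c for c in triplet]
    sub = X_df[cols].to_numpy(dtype=float)
    keep = sub.std(axis=0) > 0
    if not keep.all():
        warnings.warn("constant column(s) in subset dropped for DCCA fitness")
        sub = sub[:, keep]
        if sub.shape[1] == 0:
            return 0.0
    Xs = _standardize_columns(sub)
    ys = _standardize_columns(y.to_numpy(dtype=float)[:, None])

    rng = np.random.default_rng(cfg.seed)
    net_x = _MLP([Xs.shape[1], *cfg.hidden_layers, 1], cfg.activation, rng)
    net_y = _MLP([1, *cfg.hidden_layers, 1], cfg.activation, rng)
    opt_x = _Adam(net_x.params(), cfg.learning_rate)
    opt_y = _Adam(net_y.params(), cfg.learning_rate)

    rho = 0.0
    for _ in range(cfg.epochs):
        fa = net_x.forward(Xs)
        fb = net_y.forward(ys)
        rho, _, dfa, dfb = _corr_and_grads(fa, fb, cfg.covariance_regularizer)
        gWx, gbx = net_x.backward(dfa)
        gWy, gby = net_y.backward(dfb)
        opt_x.step(net_x.params(), net_x.grads_list(gWx, gbx))
        opt_y.step(net_y.params(), net_y.grads_list(gWy, gby))
    fa = net_x.forward(Xs)
    fb = net_y.forward(ys)
    rho, _, _, _ = _corr_and_grads(fa, fb, cfg.covariance_regularizer)
    return float(np.clip(abs(rho), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Genetic algorithm


@dataclass
class TripletFrequencyTable:
    """Per-metabolite occurrence frequency over GA repetitions."""

    strain: str
    repetitions: int
    subset_size: int
    table: pd.DataFrame  # metabolite, f, mean_fitness, selected, highlighted
    best_triplets: list[tuple[tuple[str, ...], float]]

    def top(self, k: int = 5) -> list[str]:
        return list(self.table.head(k).index)


def _random_individual(rng, n_feat, k) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(n_feat, size=k, replace=False)))


def _repair(slots: list[int], rng, n_feat) -> tuple[int, ...]:
    """Replace duplicate slots with random unused features."""
    seen, out = set(), []
    for s in slots:
        if s in seen:
            while True:
                s2 = int(rng.integers(n_feat))
                if s2 not in seen and s2 not in slots:
                    s = s2
                    break
        seen.add(s)
        out.append(s)
    return tuple(sorted(out))


def _run_one_ga(fitness, n_feat: int, ga: GAConfig, rng: np.random.Generator,
                cache: dict) -> tuple[tuple[int, ...], float]:
    """One GA repetition; returns the best individual and its fitness."""

    def fit(ind):
        if ind not in cache:
            cache[ind] = fitness(ind)
        return cache[ind]

    pop = [_random_individual(rng, n_feat, ga.subset_size) for _ in range(ga.population)]
    scores = [fit(i) for i in pop]
    best_ind, best_fit = max(zip(pop, scores), key=lambda t: t[1])

    for _ in range(ga.generations):
        order = np.argsort(scores)[::-1]
        new_pop = [pop[i] for i in order[: ga.elitism]]
        while len(new_pop) < ga.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(len(pop), size=ga.tournament_size)
                winner = max(contenders, key=lambda i: scores[i])
                parents.append(pop[winner])
            # uniform crossover per slot, then duplicate repair
            child = [
                parents[int(rng.integers(2))][s] for s in range(ga.subset_size)
            ]
            child = list(_repair(child, rng, n_feat))
            # per-slot mutation: replace with a random unused metabolite
            for s in range(ga.subset_size):
                if rng.random() < ga.mutation_rate:
                    while True:
                        cand = int(rng.integers(n_feat))
                        if cand not in child:
                            child[s] = cand
                            break
            new_pop.append(tuple(sorted(child)))
        pop = new_pop
        scores = [fit(i) for i in pop]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_fit:
            best_ind, best_fit = pop[gen_best], scores[gen_best]
    return best_ind, best_fit


def ga_select(
    a,
    y: pd.Series,
    ga: GAConfig = GAConfig(),
    dcca: DCCAConfig = DCCAConfig(),
    backend: str = "linear-cca",
    strain: str = "",
    select_threshold: int = 10,
    highlight_threshold: int = 5,
) -> TripletFrequencyTable:
    """Run many GA repetitions and count best-triplet memberships.

    Repetition ``r`` uses the seeded stream ``[ga.seed, r]``; with the same
    master seed the whole table is reproducible.  The counting identity
    sum_m f_m = subset_size x repetitions holds because only the single
    best triplet per repetition is counted.  ``selected`` flags f >
    ``select_threshold`` (the strong tier); ``highlighted`` flags f >=
    ``highlight_threshold``.
    """
    X_df = _as_feature_frame(a)
    n_feat = X_df.shape[1]
    if n_feat <= ga.subset_size:
        raise ValueError("need more metabolites than subset_size")
    y = y.loc[X_df.index]

    if backend == "linear-cca":
        fitness = LinearCCAFitness(X_df, y)
    elif backend == "dcca":
        cols = list(X_df.columns)

        def fitness(idx, _cols=cols):
            return dcca_fitness([_cols[i] for i in idx], X_df, y, cfg=dcca)
    else:
        raise ValueError("backend must be 'linear-cca' or 'dcca'")

    cache: dict = {}
    counts = np.zeros(n_feat, dtype=int)
    fit_sums = np.zeros(n_feat)
    best_triplets = []
    cols = list(X_df.columns)
    for r in range(ga.repetitions):
        rng = np.random.default_rng([ga.seed, r])
        best, bf = _run_one_ga(fitness, n_feat, ga, rng, cache)
        best_triplets.append((tuple(cols[i] for i in best), bf))
        for i in best:
            counts[i] += 1
            fit_sums[i] += bf

    with np.errstate(invalid="ignore"):
        mean_fit = np.where(counts > 0, fit_sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {"f": counts, "mean_fitness": mean_fit}, index=pd.Index(cols, name="metabolite")
    )
    table["selected"] = table["f"] > select_threshold
    table["highlighted"] = table["f"] >= highlight_threshold
    table = table.sort_values(["f", "mean_fitness"], ascending=False, kind="mergesort")
    return TripletFrequencyTable(strain, ga.repetitions, ga.subset_size, table, best_triplets)


@dataclass
class StabilityReport:
    strain: str
    repeats: int
    split_fraction: float
    frequency_vectors: pd.DataFrame    # metabolite x repeat
    rank_correlations: pd.DataFrame    # pairwise Spearman of frequencies
    top_k_overlap: float               # mean pairwise overlap fraction
    top_sets: list[list[str]]
    degenerate: bool = False


def stability_check(
    a,
    y: pd.Series,
    ga: GAConfig = GAConfig(),
    dcca: DCCAConfig = DCCAConfig(),
    backend: str = "linear-cca",
    split_fraction: float = 0.8,
    repeats: int = 5,
    top_k: int = 5,
    strain: str = "",
) -> StabilityReport:
    """Rerun the GA on random 80% genotype subsets and compare rankings."""
    X_df = _as_feature_frame(a)
    y = y.loc[X_df.index]
    n = len(X_df)
    n_train = int(round(split_fraction * n))
    if n_train < 10:
        raise ValueError("degenerate split: training subset must keep >= 10 genotypes")

    freqs, tops = {}, []
    for rep in range(repeats):
        rng = np.random.default_rng([ga.seed, 10_000 + rep])
        idx = rng.choice(n, size=n_train, replace=False)
        sub_X = X_df.iloc[np.sort(idx)]
        sub_y = y.iloc[np.sort(idx)]
        res = ga_select(sub_X, sub_y, replace(ga, seed=ga.seed + 1 + rep), dcca,
                        backend=backend, strain=strain)
        freqs[f"split{rep + 1}"] = res.table["f"].reindex(X_df.columns).fillna(0)
        tops.append(res.top(top_k))
    fv = pd.DataFrame(freqs)

    cols = list(fv.columns)
    if repeats < 2:
        rc = pd.DataFrame(np.nan, index=cols, columns=cols)
        return StabilityReport(strain, repeats, split_fraction, fv, rc,
                               np.nan, tops, degenerate=True)
    rc = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    overlaps = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho = stats.spearmanr(fv.iloc[:, i], fv.iloc[:, j]).statistic
            rc.iloc[i, j] = rc.iloc[j, i] = rho
            overlaps.append(len(set(tops[i]) & set(tops[j])) / top_k)
    return StabilityReport(strain, repeats, split_fraction, fv, rc,
                           float(np.mean(overlaps)), tops)
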