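"""Partial-least-squares regression / discriminant analysis and networks.

PLS regresses the (standardized) genotype x metabolite matrix on one or
more inhibition responses through a small number of latent components
(classical two-block NIPALS with deflation).  Association networks are
built from the *relevance* similarity — the correlation of each metabolite
and each response with the shared latent components, summed over
components — thresholded at a per-strain absolute cutoff (0.40 NF /
0.35 NV / 0.38 NM / 0.45 NU; 0.35 or 0.40 for the quartile PLS-DA
network).  Signs are fixed deterministically (largest-magnitude weight
positive) so networks are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .preprocess import QuartileAssignment

__all__ = [
    "PLSModel",
    "fit_pls",
    "relevance_similarity",
    "build_network",
    "plsda_quartiles",
    "DEFAULT_EDGE_CUTOFFS",
    "graph_to_edgelist",
]

#: Per-strain network edge cutoffs (absolute relevance score).
DEFAULT_EDGE_CUTOFFS = {"NF": 0.40, "NV": 0.35, "NM": 0.38, "NU": 0.45}


@dataclass
class PLSModel:
    x_weights: pd.DataFrame    # metabolite x component (unit norm)
    x_loadings: pd.DataFrame   # metabolite x component
    y_loadings: pd.DataFrame   # response x component
    scores: pd.DataFrame       # genotype x component
    coefficients: pd.DataFrame  # metabolite x response, standardized scale
    x_mean: pd.Series
    x_std: pd.Series
    y_mean: pd.Series
    y_std: pd.Series
    x_residual: np.ndarray
    y_names: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = (X[self.x_weights.index] - self.x_mean) / self.x_std
        Ys = Xs.to_numpy() @ self.coefficients.to_numpy()
        return pd.DataFrame(
            Ys * self.y_std.to_numpy() + self.y_mean.to_numpy(),
            index=X.index, columns=self.y_names,
        )


def _standardize(df: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=1)
    std = std.where(std > 0, 1.0)
    return ((df - mean) / std).to_numpy(dtype=float), mean, std


def fit_pls(a, y, n_components: int = 2) -> PLSModel:
    """Two-block NIPALS PLS on standardized data.

    ``a`` is an :class:`AbundanceMatrix` or a plain DataFrame; ``y`` a
    Series (PLS1) or DataFrame (PLS2, e.g. one-hot class block).  Both
    blocks are centered to zero mean and unit variance.  Components are
    extracted by iterative deflation; each weight vector's sign is fixed
    by forcing its largest-magnitude entry positive.
    """
    X_df = a.values if isinstance(a, AbundanceMatrix) else a
    if isinstance(y, pd.Series):
        Y_df = y.to_frame(y.name or "response")
    else:
        Y_df = y.copy()
    Y_df = Y_df.loc[X_df.index]
    if int(n_components) < 1:
        raise ValueError("n_components must be >= 1")
    n_components = int(n_components)
    if n_components > min(X_df.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if (Y_df.std(axis=0, ddof=1) == 0).any():
        raise ValueError("zero-variance response")

    X, x_mean, x_std = _standardize(X_df)
    Y, y_mean, y_std = _standardize(Y_df)
    n, p = X.shape
    q = Y.shape[1]

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    Xr, Yr = X.copy(), Y.copy()

    for k in range(n_components):
        u = Yr[:, np.argmax(Yr.var(axis=0))].copy()
        w = np.zeros(p)
        for _ in range(500):
            w_new = Xr.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            t = Xr @ w_new
            c = Yr.T @ t / (t @ t)
            denom = c @ c
            u_new = Yr @ c / denom if denom > 0 else u
            if np.linalg.norm(w_new - w) < 1e-12:
                w = w_new
                break
            w, u = w_new, u_new
        # deterministic sign: largest-magnitude weight entry positive
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w = -w
        t = Xr @ w
        tt = t @ t
        if tt == 0:
            W, P, C, T = W[:, :k], P[:, :k], C[:, :k], T[:, :k]
            break
        p_load = Xr.T @ t / tt
        c = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, c)
        W[:, k], P[:, k], C[:, k], T[:, k] = w, p_load, c, t

    k = T.shape[1]
    comps = [f"comp{i + 1}" for i in range(k)]
    # B = W (P'W)^{-1} C'
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return PLSModel(
        x_weights=pd.DataFrame(W, index=X_df.columns, columns=comps),
        x_loadings=pd.DataFrame(P, index=X_df.columns, columns=comps),
        y_loadings=pd.DataFrame(C, index=Y_df.columns, columns=comps),
        scores=pd.DataFrame(T, index=X_df.index, columns=comps),
        coefficients=pd.DataFrame(B, index=X_df.columns, columns=Y_df.columns),
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        x_residual=Xr, y_names=list(Y_df.columns),
    )


def _safe_corr(M: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Column-wise correlation of M's columns with T's columns."""
    Mc = M - M.mean(axis=0)
    Tc = T - T.mean(axis=0)
    ms = np.linalg.norm(Mc, axis=0)
    ts = np.linalg.norm(Tc, axis=0)
    ms[ms == 0] = np.inf
    ts[ts == 0] = np.inf
    return (Mc.T @ Tc) / np.outer(ms, ts)


def relevance_similarity(model: PLSModel, a, y) -> pd.DataFrame:
    """Relevance-network similarity: sum_h cor(X_j, t_h) * cor(Y_k, t_h).

    Scores lie in [-1, 1] and play the role of the "correlation" whose
    absolute value is thresholded when drawing the network.
    """
    X_df = a.values if isinstance(a, AbundanceMatrix) else a
    Y_df = y.to_frame(y.name or "response") if isinstance(y, pd.Series) else y
    T = model.scores.to_numpy()
    cx = _safe_corr(X_df.loc[model.scores.index].to_numpy(dtype=float), T)
    cy = _safe_corr(Y_df.loc[model.scores.index].to_numpy(dtype=float), T)
    sim = cx @ cy.T
    return pd.DataFrame(np.clip(sim, -1.0, 1.0), index=X_df.columns, columns=Y_df.columns)


def build_network(
    similarity: pd.DataFrame,
    cutoff: float,
    metabolite_meta: pd.DataFrame | None = None,
    dl_selected: set[str] | None = None,
) -> nx.Graph:
    """Threshold a metabolite x response similarity matrix into a graph.

    Edges keep pairs with |score| >= cutoff; edge attributes carry the
    signed weight and sign; metabolite nodes carry chemical class and an
    optional deep-learning-selected flag.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    g = nx.Graph()
    dl_selected = dl_selected or set()
    for resp in similarity.columns:
        g.add_node(str(resp), kind="response")
    for met in similarity.index:
        cls = ""
        if metabolite_meta is not None and met in metabolite_meta.index:
            cls = str(metabolite_meta.at[met, "chemical_class"])
        g.add_node(str(met), kind="metabolite", chemical_class=cls,
                   dl_selected=met in dl_selected)
    for met in similarity.index:
        for resp in similarity.columns:
            w = float(similarity.at[met, resp])
            if abs(w) >= cutoff and str(met) != str(resp):
                g.add_edge(str(met), str(resp), weight=w,
                           sign="positive" if w >= 0 else "negative")
    # drop isolated metabolite nodes for a tidy edge-driven graph
    isolated = [n for n, d in g.degree() if d == 0 and g.nodes[n]["kind"] == "metabolite"]
    g.remove_nodes_from(isolated)
    return g


def graph_to_edgelist(g: nx.Graph) -> pd.DataFrame:
    rows = [
        (u, v, d["weight"], d["sign"]) for u, v, d in
        sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])


def plsda_quartiles(
    a: AbundanceMatrix,
    q: QuartileAssignment,
    n_components: int = 2,
    cutoff: float = 0.40,
    dl_selected: set[str] | None = None,
) -> tuple[PLSModel, nx.Graph, pd.Series]:
    """PLS-DA on inhibition quartiles with a thresholded relevance network.

    The quartile labels become a one-hot response block; returns the fitted
    model, the network (deep-learning-selected metabolites flagged on
    nodes) and the nearest-class-score training classification.
    """
    counts = q.labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each quartile needs >= 2 genotypes for PLS-DA")
    onehot = pd.get_dummies(q.labels).astype(float)
    onehot = onehot.loc[a.values.index]
    model = fit_pls(a, onehot, n_components=n_components)
    sim = relevance_similarity(model, a, onehot)
    graph = build_network(sim, cutoff, a.metabolite_meta, dl_selected)
    pred = model.predict(a.values)
    assigned = pred.idxmax(axis=1).rename("predicted_quartile")
    return model, graph, assigned
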