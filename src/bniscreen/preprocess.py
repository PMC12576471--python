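"""Normalization, group contrasts, ordination and class aggregation.

These are the table-level transforms applied to abundance matrices before
any association analysis: weight normalization + log transform for GC-MS
tables, sample-centric abundance balancing for LC-MS tables, the signed
fold-change / Wilcoxon volcano screen between the two origin groups,
presence/absence (Venn) membership, PCA, chemical-class aggregation, and
the quartile ranking of genotypes by mean inhibition capacity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, InhibitionMatrix

__all__ = [
    "normalize_gcms",
    "abundance_balance",
    "volcano",
    "VolcanoResult",
    "venn_membership",
    "pca",
    "OrdinationResult",
    "aggregate_by_class",
    "quartiles_by_inhibition",
    "QuartileAssignment",
]


def normalize_gcms(a: AbundanceMatrix) -> AbundanceMatrix:
    """Weight-normalize then log10(x + 1)-transform a GC-MS peak-area table.

    Each genotype row is divided by its root dry weight (grams) first and
    the +1 offset is applied inside the log, so zeros ("not detected") map
    exactly to 0.
    """
    w = a.genotype_meta["root_dry_weight"]
    if w.isna().any():
        missing = list(w.index[w.isna()])
        raise ValueError(f"missing root dry weight for genotypes: {missing}")
    if (w <= 0).any():
        bad = list(w.index[w <= 0])
        raise ValueError(f"non-positive root dry weight for genotypes: {bad}")
    out = np.log10(a.values.div(w, axis=0) + 1.0)
    return a.copy_with(out)


def abundance_balance(a: AbundanceMatrix) -> AbundanceMatrix:
    """Sample-centric balancing: row proportions x mean total intensity.

    Every genotype row is divided by its total, then multiplied by the
    grand mean of the original row totals, so row sums become equal while
    the total matrix intensity is conserved.
    """
    totals = a.values.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero abundance rows for genotypes: {bad}")
    out = a.values.div(totals, axis=0) * totals.mean()
    return a.copy_with(out)


@dataclass
class VolcanoResult:
    """Per-metabolite signed fold change, Wilcoxon p and category."""

    table: pd.DataFrame  # columns: signed_fold_change, p_value, category
    group_a: str
    group_b: str
    fc_threshold: float
    p_threshold: float


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when both groups are small."""
    method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the tie-corrected normal
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def volcano(
    a: AbundanceMatrix,
    group_col: str = "origin",
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> VolcanoResult:
    """Signed fold-change / Wilcoxon screen between the two origin groups.

    Fold change is the signed ratio of group means: ``mA/mB`` when A is
    enriched, ``-(mB/mA)`` otherwise (a raw ratio can never be <= -2; the
    sign encodes the enriched group).  Categories: ``up_A`` when
    FC >= +threshold and p <= alpha, ``up_B`` when FC <= -threshold and
    p <= alpha, else ``ns``.
    """
    groups = a.genotype_meta[group_col]
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"volcano needs exactly two groups, got {labels}")
    ga, gb = labels
    idx_a = groups[groups == ga].index
    idx_b = groups[groups == gb].index
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 genotypes")

    A = a.values.loc[idx_a]
    B = a.values.loc[idx_b]
    ma, mb = A.mean(axis=0), B.mean(axis=0)

    records = []
    for m in a.metabolites:
        x, y = A[m].to_numpy(), B[m].to_numpy()
        va, vb = ma[m], mb[m]
        if va == 0 and vb == 0:
            fc = 1.0
        elif vb == 0:
            fc = np.inf
        elif va == 0:
            fc = -np.inf
        else:
            fc = va / vb if va >= vb else -(vb / va)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            p = _rank_sum_p(x, y)
        if fc >= fc_threshold and p <= p_threshold:
            cat = "up_A"
        elif fc <= -fc_threshold and p <= p_threshold:
            cat = "up_B"
        else:
            cat = "ns"
        records.append((m, fc, p, cat))
    table = pd.DataFrame(
        records, columns=["metabolite", "signed_fold_change", "p_value", "category"]
    ).set_index("metabolite")
    return VolcanoResult(table, ga, gb, fc_threshold, p_threshold)


def venn_membership(
    a: AbundanceMatrix,
    presence_fraction: float = 0.5,
    group_col: str = "origin",
) -> pd.Series:
    """Per-feature membership in {A_only, B_only, shared, absent}.

    A feature is "present" in a group when it is nonzero in at least
    ``presence_fraction`` of that group's genotypes.
    """
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must be in (0, 1]")
    groups = a.genotype_meta[group_col]
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"venn_membership needs exactly two groups, got {labels}")
    ga, gb = labels
    in_a = (a.values.loc[groups == ga] > 0).mean(axis=0) >= presence_fraction
    in_b = (a.values.loc[groups == gb] > 0).mean(axis=0) >= presence_fraction
    out = pd.Series("absent", index=a.values.columns, name="membership")
    out[in_a & in_b] = "shared"
    out[in_a & ~in_b] = "A_only"
    out[~in_a & in_b] = "B_only"
    return out


@dataclass
class OrdinationResult:
    scores: pd.DataFrame        # genotype x component
    loadings: pd.DataFrame      # metabolite x component (orthonormal)
    variance_explained: np.ndarray  # fraction per component, non-increasing


def pca(a: AbundanceMatrix, scale: bool = False, n_components: int | None = None) -> OrdinationResult:
    """Centered (optionally unit-variance-scaled) PCA via SVD."""
    X = a.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca needs >= 2 genotypes and >= 2 metabolites")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("constant matrix: PCA undefined")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components or len(S), len(S))
    var = S**2
    frac = var / var.sum()
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * S[:k], index=a.values.index, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=a.values.columns, columns=comps)
    return OrdinationResult(scores, loadings, frac[:k])


def aggregate_by_class(a: AbundanceMatrix) -> pd.DataFrame:
    """Class x genotype means, each class row scaled to sum 1 over genotypes."""
    classes = a.metabolite_meta.reindex(a.metabolites)["chemical_class"]
    if classes.isna().any():
        warnings.warn("unlabeled metabolites assigned class 'other'")
        classes = classes.fillna("other")
    means = a.values.T.groupby(classes.values).mean()  # class x genotype
    totals = means.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("class with all-zero means cannot be sum-scaled")
    out = means.div(totals, axis=0)
    out.index.name = "chemical_class"
    return out


@dataclass
class QuartileAssignment:
    """Genotype -> Q1..Q4 label; Q1 = highest mean inhibition capacity."""

    labels: pd.Series        # index genotype, values "Q1".."Q4"
    mean_inhibition: pd.Series

    def members(self, q: str) -> list[str]:
        return list(self.labels.index[self.labels == q])


def quartiles_by_inhibition(inh: InhibitionMatrix) -> QuartileAssignment:
    """Rank genotypes by mean AOI% across strains and split into quartiles.

    Sizes differ by at most one; ties in mean inhibition are broken by
    genotype id (stable, documented).  44 genotypes give 11 per quartile.
    """
    mean = inh.mean_matrix().mean(axis=1)
    if len(mean) < 4:
        raise ValueError("quartile assignment needs >= 4 genotypes")
    order = mean.to_frame("m").reset_index()
    order = order.sort_values(["m", "genotype"], ascending=[False, True])
    chunks = np.array_split(order["genotype"].to_numpy(), 4)
    labels = pd.Series(index=mean.index, dtype=object, name="quartile")
    for i, chunk in enumerate(chunks):
        labels.loc[chunk] = f"Q{i + 1}"
    return QuartileAssignment(labels, mean)
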