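"""Metabolite-by-metabolite Spearman screening against per-strain AOI%.

Each annotated metabolite's abundance across genotypes is rank-correlated
with the mean inhibition of each reporter strain.  Flags follow the
screen's volcano-style rule: positive when rho >= r_pos and p <= alpha,
negative when rho <= r_neg and p <= alpha (the negative cutoff is
strain-specific: -0.45 for NF and NM, -0.40 for NV and NU).  No multiple-
testing correction enters the flags; a Benjamini-Hochberg column is
emitted alongside for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, InhibitionMatrix

__all__ = [
    "StrainThresholds",
    "DEFAULT_THRESHOLDS",
    "spearman_screen",
    "CorrelationTable",
    "correlation_scatter_table",
]


@dataclass(frozen=True)
class StrainThresholds:
    r_pos: float = 0.40
    r_neg: float = -0.40
    alpha: float = 0.05


#: Per-strain defaults: asymmetric negative cutoffs as reported per panel.
DEFAULT_THRESHOLDS: dict[str, StrainThresholds] = {
    "NF": StrainThresholds(0.40, -0.45, 0.05),
    "NV": StrainThresholds(0.40, -0.40, 0.05),
    "NM": StrainThresholds(0.40, -0.45, 0.05),
    "NU": StrainThresholds(0.40, -0.40, 0.05),
}


@dataclass
class CorrelationTable:
    """Long table of per-(metabolite, strain) rho, p, n and flag."""

    table: pd.DataFrame  # columns: metabolite, strain, rho, p_value, p_bh, n, flag
    thresholds: dict[str, StrainThresholds]

    def for_strain(self, strain: str) -> pd.DataFrame:
        return self.table[self.table["strain"] == strain].set_index("metabolite")


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks) with two-sided t-approximation p."""
    n = len(x)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = np.corrcoef(rx, ry)[0, 1]
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def spearman_screen(
    a: AbundanceMatrix,
    inh: InhibitionMatrix,
    thresholds: dict[str, StrainThresholds] | None = None,
) -> CorrelationTable:
    """Correlate every metabolite with every strain's mean AOI%.

    Genotypes are matched by id; >= 5 shared genotypes are required.
    Constant metabolite columns yield an undefined rho and are flagged
    ``ns`` with a warning.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    mean = inh.mean_matrix()
    shared = a.values.index.intersection(mean.index)
    if len(shared) < 5:
        raise ValueError("need >= 5 shared genotypes between abundance and inhibition")
    X = a.values.loc[shared]
    Y = mean.loc[shared]

    rows = []
    n_constant = 0
    for strain in Y.columns:
        th = thresholds.get(strain, StrainThresholds())
        y = Y[strain].to_numpy(dtype=float)
        for m in X.columns:
            x = X[m].to_numpy(dtype=float)
            rho, p = _spearman(x, y)
            if np.isnan(rho):
                n_constant += 1
                rows.append((m, strain, np.nan, np.nan, len(shared), "ns"))
                continue
            if rho >= th.r_pos and p <= th.alpha:
                flag = "positive"
            elif rho <= th.r_neg and p <= th.alpha:
                flag = "negative"
            else:
                flag = "ns"
            rows.append((m, strain, rho, p, len(shared), flag))
    if n_constant:
        warnings.warn(f"{n_constant} constant metabolite column(s): rho undefined, flagged ns")

    table = pd.DataFrame(rows, columns=["metabolite", "strain", "rho", "p_value", "n", "flag"])
    p_bh = np.full(len(table), np.nan)
    ok = table["p_value"].notna().to_numpy()
    if ok.any():
        p_bh[ok] = multipletests(table.loc[ok, "p_value"], method="fdr_bh")[1]
    table.insert(4, "p_bh", p_bh)
    return CorrelationTable(table, thresholds)


def correlation_scatter_table(
    ct: CorrelationTable,
    a: AbundanceMatrix,
    inh: InhibitionMatrix,
    strain: str,
    top_k: int = 10,
) -> pd.DataFrame:
    """Per-genotype (abundance, AOI%, origin) rows for the top correlates.

    The top_k significant metabolites (largest |rho| among flagged rows) of
    the given strain are expanded into a long table suitable for scatter
    panels.  If fewer than top_k are significant, all are returned.
    """
    sub = ct.table[(ct.table["strain"] == strain) & (ct.table["flag"] != "ns")]
    if top_k == 0 or sub.empty:
        return pd.DataFrame(columns=["metabolite", "genotype", "abundance", "aoi", "origin", "rho"])
    sub = sub.reindex(sub["rho"].abs().sort_values(ascending=False).index)
    chosen = sub.head(top_k)
    y = inh.strain_vector(strain)
    shared = a.values.index.intersection(y.index)
    origin = a.genotype_meta["origin"]
    rows = []
    for _, r in chosen.iterrows():
        m = r["metabolite"]
        for g in shared:
            rows.append((m, g, a.values.at[g, m], y[g], origin[g], r["rho"]))
    return pd.DataFrame(rows, columns=["metabolite", "genotype", "abundance", "aoi", "origin", "rho"])
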