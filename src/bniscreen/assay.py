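"""Bioassay quantification: nitrite calibration, AOI%, EC50, group stats.

The fast-track nitrification-inhibition assay reads nitrite colorimetrically
(540 nm) from microplate cultures of ammonia-oxidizing strains exposed to an
inhibitor dilution series or root-exudate treatments.  This module converts
readings to activity, computes the ammonia-oxidation-inhibition percentage
(AOI%) either from a single timepoint or from nitrite-vs-time slopes, fits
EC50 by a bounded four-parameter logistic (with log-linear interpolation
fallback), and provides the nonparametric group comparisons used to contrast
strains, domains and genotype origins.

Negative AOI% (growth stimulation) is retained everywhere, never truncated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import DoseResponseSeries, InhibitionMatrix

__all__ = [
    "nitrite_from_absorbance",
    "aoi_single_timepoint",
    "aoi_slope_based",
    "fit_ec50",
    "DoseResponseFit",
    "compare_strains",
    "StatTestResult",
    "dunn_posthoc",
    "compact_letter_display",
    "cluster_inhibition",
    "ClusterResult",
]


def nitrite_from_absorbance(absorbance, standards) -> np.ndarray:
    """Inverse-predict nitrite (uM) from a linear standard curve.

    ``standards`` is a sequence of (absorbance, concentration) pairs;
    an ordinary least-squares line is fitted and inverted.  Negative
    predictions are clipped to 0 with a warning.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[0] < 3:
        raise ValueError("need >= 3 (absorbance, concentration) standards")
    au, conc = standards[:, 0], standards[:, 1]
    if np.ptp(au) == 0:
        raise ValueError("standards have zero absorbance variance")
    slope, intercept = np.polyfit(au, conc, 1)
    pred = slope * np.asarray(absorbance, dtype=float) + intercept
    if np.any(pred < 0):
        warnings.warn("absorbance below blank: clipping predicted nitrite to 0")
        pred = np.clip(pred, 0.0, None)
    return pred


def aoi_single_timepoint(treated, control) -> float:
    """AOI% = (1 - mean(treated)/mean(control)) x 100.

    100% means complete inhibition of nitrite production; negative values
    mean stimulation.  Unit-invariant (any common nitrite unit cancels).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError("control mean nitrite must be positive")
    return float((1.0 - treated.mean() / cmean) * 100.0)


def aoi_replicate_level(treated, control) -> np.ndarray:
    """Per-replicate AOI% of each treated reading against the control mean."""
    control = np.asarray(control, dtype=float)
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError("control mean nitrite must be positive")
    return (1.0 - np.asarray(treated, dtype=float) / cmean) * 100.0


def aoi_slope_based(series: DoseResponseSeries) -> pd.DataFrame:
    """AOI% per concentration from nitrite-vs-time regression slopes.

    For each dose, nitrite readings (pooled over replicates) are regressed
    on time; AOI%_c = (1 - slope_c / slope_0) x 100.  Requires >= 3
    timepoints and a strictly positive control slope.
    """
    df = series.readings
    if df["timepoint"].nunique() < 3:
        raise ValueError("slope-based AOI needs >= 3 timepoints")
    slopes = {}
    for c, grp in df.groupby("concentration"):
        slopes[c] = np.polyfit(grp["timepoint"], grp["nitrite"], 1)[0]
    s0 = slopes.get(0.0)
    if s0 is None or s0 <= 0:
        raise ValueError("control slope must be positive (inactive culture?)")
    rows = [
        (c, s, (1.0 - s / s0) * 100.0)
        for c, s in sorted(slopes.items())
        if c > 0
    ]
    return pd.DataFrame(rows, columns=["concentration", "slope", "aoi"])


@dataclass
class DoseResponseFit:
    model: str                    # "four_param_logistic" | "slope_interpolation"
    ec50: float
    hill: float | None
    bottom: float | None
    top: float | None
    residual_sse: float
    converged: bool
    extrapolated: bool = False


def _fpl(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def _interp_ec50(conc: np.ndarray, aoi: np.ndarray) -> float | None:
    """Log-linear interpolation of the first 50% crossing, if bracketed."""
    order = np.argsort(conc)
    c, a = conc[order], aoi[order]
    for i in range(len(c) - 1):
        lo, hi = a[i], a[i + 1]
        if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
            f = (50.0 - lo) / (hi - lo)
            return float(10 ** (np.log10(c[i]) + f * (np.log10(c[i + 1]) - np.log10(c[i]))))
    return None


def fit_ec50(aoi_by_conc, model: str = "four_param_logistic") -> DoseResponseFit:
    """Fit EC50 from (concentration, AOI%) pairs.

    A four-parameter logistic ``AOI(c) = bottom + (top - bottom) /
    (1 + (ec50/c)^h)`` is fitted on AOI vs log10 concentration by bounded
    nonlinear least squares (bottom in [-40, 20], top in [60, 110]), with a
    small deterministic multi-start grid to dodge local minima.  The
    reported ``ec50`` is the concentration where the *fitted curve crosses
    50%*.  If the fit fails, falls back to log-linear interpolation between
    the doses bracketing 50%.
    """
    pairs = np.asarray(aoi_by_conc, dtype=float)
    pairs = pairs[pairs[:, 0] > 0]
    if len(np.unique(pairs[:, 0])) < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations")
    conc, aoi = pairs[:, 0], pairs[:, 1]
    spans_50 = aoi.min() < 50.0 < aoi.max()
    logc = np.log10(conc)

    best = None
    if model == "four_param_logistic":
        for lec0, h0 in itertools.product(
            [logc.min(), np.median(logc), logc.max()], [1.0]
        ):
            try:
                popt, _ = optimize.curve_fit(
                    _fpl, logc, aoi,
                    p0=[0.0, 100.0, lec0, h0],
                    bounds=([-40.0, 60.0, logc.min() - 2, 0.05],
                            [20.0, 110.0, logc.max() + 2, 10.0]),
                    maxfev=10000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((_fpl(logc, *popt) - aoi) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)

    if best is not None:
        bottom, top, log_ec50, hill = best[0]
        # concentration where the fitted curve crosses AOI = 50%
        if bottom < 50.0 < top:
            ratio = (top - bottom) / (50.0 - bottom) - 1.0
            c50 = 10 ** (log_ec50 - np.log10(ratio) / hill)
            if not spans_50 and not (conc.min() <= c50 <= conc.max()):
                # crossing lies outside the tested doses and the data never
                # approach 50%: pure extrapolation, not an estimate
                c50 = None
        else:
            c50 = None
        if c50 is not None:
            return DoseResponseFit(
                "four_param_logistic", float(c50), float(hill),
                float(bottom), float(top), best[1], True,
                extrapolated=not spans_50,
            )

    c50 = _interp_ec50(conc, aoi)
    if c50 is None:
        raise ValueError("EC50 not estimable: no fit and no bracketing dose pair")
    sse = float("nan")
    return DoseResponseFit("slope_interpolation", c50, None, None, None, sse,
                           converged=False, extrapolated=not spans_50)


# ---------------------------------------------------------------------------
# Group statistics


@dataclass
class StatTestResult:
    test: str                     # kruskal_wallis | wilcoxon_rank_sum
    statistic: float              # H for KW, rank-sum W for Wilcoxon
    p_value: float
    group_letters: dict[str, str] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None  # Dunn-Bonferroni table
    u_statistic: float | None = None      # Mann-Whitney U, for reference


def dunn_posthoc(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with Bonferroni adjustment."""
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks, pos = {}, 0
    for g in names:
        mean_ranks[g] = ranks[pos: pos + sizes[g]].mean()
        pos += sizes[g]
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_sum = np.sum(counts**3 - counts)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)))
            * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append((g1, g2, z, p, min(1.0, p * m)))
    return pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw", "p_adj"])


def compact_letter_display(names: list[str], pairwise: pd.DataFrame,
                           means: dict[str, float], alpha: float = 0.05) -> dict[str, str]:
    """Assign letters so groups share a letter iff not significantly different.

    Letters are the maximal cliques of the non-significance graph, ordered
    by descending group mean so 'a' tags the highest group.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    for _, row in pairwise.iterrows():
        if row["p_adj"] >= alpha:
            g.add_edge(row["group1"], row["group2"])
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[x] for x in c))
    letters = {n: "" for n in names}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for n in clique:
            letters[n] += ch
    return letters


def compare_strains(
    inh: InhibitionMatrix,
    grouping: str = "strain",
    alpha: float = 0.05,
    use_replicates: bool = True,
) -> StatTestResult:
    """Kruskal-Wallis (+ Dunn-Bonferroni + letters) or Wilcoxon rank-sum.

    ``grouping`` may be ``strain``, ``domain`` (requires strain metadata) or
    ``origin``-style metadata column attached beforehand via a ``group``
    column on the replicate table.  Two groups are compared by the Wilcoxon
    rank-sum test (W = rank sum of the first-listed group; exact for small
    samples); more groups by the tie-corrected Kruskal-Wallis H.
    """
    df = inh.replicates.copy()
    if grouping == "strain":
        df["group"] = df["strain"]
    elif grouping == "domain":
        if inh.strain_meta is None:
            raise ValueError("domain grouping requires strain metadata")
        df["group"] = df["strain"].map(inh.strain_meta["domain"])
    elif grouping in df.columns:
        df["group"] = df[grouping]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if not use_replicates:
        df = df.groupby(["genotype", "group"], as_index=False)["aoi"].mean()

    names = list(pd.unique(df["group"]))
    groups = {g: df.loc[df["group"] == g, "aoi"].to_numpy() for g in names}
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"empty group {g!r}")
    if len(names) < 2 or min(len(v) for v in groups.values()) < 3:
        raise ValueError("need >= 2 groups with >= 3 values each")

    if len(names) == 2:
        x, y = groups[names[0]], groups[names[1]]
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w = float(ranks[: len(x)].sum())
        method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
        try:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u = float(res.statistic)
        return StatTestResult("wilcoxon_rank_sum", w, float(res.pvalue), u_statistic=u)

    if all(np.array_equal(groups[names[0]], groups[g]) for g in names[1:]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*[groups[g] for g in names])
    pairwise = dunn_posthoc(groups, alpha)
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    letters = compact_letter_display(names, pairwise, means, alpha)
    return StatTestResult("kruskal_wallis", float(h), float(p), letters, pairwise)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]


def cluster_inhibition(
    inh: InhibitionMatrix,
    method: str = "complete",
    impute_missing: bool = False,
) -> ClusterResult:
    """Hierarchical clustering of the mean AOI% matrix (Euclidean distance).

    Complete linkage by default (configurable).  Leaf order is made
    deterministic by seriating with scipy's optimal ordering disabled and
    breaking ties through the stable input order (ids sorted beforehand).
    """
    m = inh.mean_matrix().sort_index(axis=0).sort_index(axis=1)
    if m.isna().any().any():
        if not impute_missing:
            raise ValueError("mean AOI matrix has missing values; set impute_missing")
        m = m.fillna(m.mean())
    X = m.to_numpy()
    row_l = hierarchy.linkage(pdist(X), method=method)
    col_l = hierarchy.linkage(pdist(X.T), method=method)
    row_order = [m.index[i] for i in hierarchy.leaves_list(row_l)]
    col_order = [m.columns[i] for i in hierarchy.leaves_list(col_l)]
    return ClusterResult(row_l, col_l, row_order, col_order)
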