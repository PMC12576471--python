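"""Seed-reproducible synthetic root-exudate studies with planted truth.

The generator emulates the statistical structure of a two-origin wheat
root-exudate screen: 44 genotypes (20 "A" / 24 "B", standing for the two
geographic origins), ~357 annotated metabolites in ~12 chemical classes,
and four ammonia-oxidizer reporter strains (two archaeal: NF, NV; two
bacterial: NM, NU).  A :class:`PlantedTruth` plants (i) per-strain additive
inhibitory metabolites, (ii) one *synergistic triplet* whose members are
individually weak but jointly strong — the signal a combinatorial selector
must detect, (iii) stimulators with negative weights, and (iv) origin-shifted
metabolites that create fold-change / ordination structure.

Inhibition is built as

    AOI%(g, s) = clip( sum_{m in active_s} w_m sigma(z_gm)
                       + w_syn prod_{m in triplet} sigma(z_gm)
                       + sum_{m in stim} w'_m sigma(z_gm) + eps,  -40, 100 )

where ``z`` is the column-standardized log10 abundance and ``sigma`` the
logistic squashing.  AOI% is bounded above by 100 (complete inhibition) and
below by -40 (growth stimulation; real screens observe both).

Everything is driven by integer seeds through ``numpy.random.default_rng``;
regenerating with the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, DoseResponseSeries, InhibitionMatrix

__all__ = [
    "StudyDesign",
    "PlantedTruth",
    "SyntheticStudy",
    "default_truth",
    "simulate_abundances",
    "simulate_inhibition",
    "simulate_doseresponse",
    "standardized_log_abundance",
    "make_study",
]

DEFAULT_STRAINS = {"NF": "AOA", "NV": "AOA", "NM": "AOB", "NU": "AOB"}

DEFAULT_CLASSES = [
    "flavonoids", "vitamins", "quinones", "phenylpropanoids", "amines",
    "carbohydrates", "terpenoids", "nitrogenous_bases", "lipids",
    "carboxylic_acids", "alkaloids", "amino_acids_and_derivatives",
]


@dataclass
class StudyDesign:
    """Shape and seed of a synthetic study (defaults = the screened cohort)."""

    n_genotypes: int = 44
    origin_split: tuple[int, int] = (20, 24)  # labels "A" / "B"
    n_metabolites: int = 357
    n_unannotated_features: int = 0
    n_classes: int = 12
    strains: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_STRAINS))
    zero_inflation: float = 0.10
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.origin_split) != self.n_genotypes:
            raise ValueError("origin_split must sum to n_genotypes")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if self.n_classes > self.n_metabolites:
            self.n_classes = self.n_metabolites  # small designs: one class per metabolite

    @property
    def genotype_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genotypes)]

    @property
    def metabolite_ids(self) -> list[str]:
        ann = [f"m{i + 1}" for i in range(self.n_metabolites)]
        feats = [f"f{i + 1}" for i in range(self.n_unannotated_features)]
        return ann + feats

    @property
    def origins(self) -> list[str]:
        nA, nB = self.origin_split
        return ["A"] * nA + ["B"] * nB


@dataclass
class PlantedTruth:
    """Ground-truth effects planted into a synthetic study.

    ``active_sets`` maps strain -> {metabolite id: additive weight in AOI%
    units}; ``synergy_triplet`` is a 3-tuple whose *product* term (weight
    ``synergy_weight``) applies to every strain; ``stimulators`` carry
    negative weights; ``origin_shifted`` maps metabolite -> log10 shift
    applied to origin "A" (negative = enriched in "B").
    """

    active_sets: dict[str, dict[str, float]] = field(default_factory=dict)
    synergy_triplet: tuple[str, str, str] | None = None
    synergy_weight: float = 0.0
    stimulators: dict[str, float] = field(default_factory=dict)
    origin_shifted: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 5.0

    def referenced_metabolites(self) -> set[str]:
        ids: set[str] = set()
        for d in self.active_sets.values():
            ids.update(d)
        if self.synergy_triplet is not None:
            ids.update(self.synergy_triplet)
        ids.update(self.stimulators)
        ids.update(self.origin_shifted)
        return ids


@dataclass
class SyntheticStudy:
    abundance: AbundanceMatrix
    inhibition: InhibitionMatrix
    truth: PlantedTruth
    design: StudyDesign


def default_truth(design: StudyDesign, n_active_per_strain: int = 5) -> PlantedTruth:
    """The stated-world planted truth for the default study.

    Per strain: ``n_active_per_strain`` additive inhibitors at weight 15.
    One shared synergistic triplet: members individually weak (weight 8)
    but jointly strong (product weight 60).  Three stimulators at -10.
    ~20 origin-shifted metabolites at +/-1 log10 unit.  Replicate noise
    sd 5 AOI units.
    """
    rng = np.random.default_rng([design.seed, 911])
    mids = design.metabolite_ids[: design.n_metabolites]
    perm = [str(m) for m in rng.permutation(mids)]
    triplet = tuple(perm[:3])
    active: dict[str, dict[str, float]] = {}
    pos = 3
    for s in design.strains:
        chosen = perm[pos: pos + n_active_per_strain]
        pos += n_active_per_strain
        weights = {m: 15.0 for m in chosen}
        # triplet members are individually weak in every strain
        for m in triplet:
            weights[m] = 8.0
        active[s] = weights
    stim = {m: -10.0 for m in perm[pos: pos + 3]}
    pos += 3
    n_shift = min(20, len(perm) - pos)
    shifts = {
        m: float(rng.choice([-1.0, 1.0]))
        for m in perm[pos: pos + n_shift]
    }
    return PlantedTruth(
        active_sets=active,
        synergy_triplet=triplet,
        synergy_weight=60.0,
        stimulators=stim,
        origin_shifted=shifts,
        noise_sd=5.0,
    )


def _check_truth_ids(truth: PlantedTruth, metabolite_ids) -> None:
    unknown = truth.referenced_metabolites() - set(metabolite_ids)
    if unknown:
        raise ValueError(f"planted truth references unknown metabolites: {sorted(unknown)[:5]}")


def simulate_abundances(design: StudyDesign, truth: PlantedTruth | None = None) -> AbundanceMatrix:
    """Generate log-normal abundances with planted origin shifts.

    Per metabolite the log10 mean is drawn N(5, 1); per chemical class a
    log10 sd is drawn U[0.2, 0.6].  Origin-shifted metabolites receive an
    additive log10 shift in origin "A" (a +/-1 shift implies an expected
    fold change of 10 on the raw scale, comfortably past the |FC| >= 2
    screen).  A fraction of entries (default 10%) is zeroed to emulate
    "feature not detected" for presence/absence logic.
    """
    truth = truth or PlantedTruth(noise_sd=0.0)
    mids = design.metabolite_ids
    _check_truth_ids(truth, mids)
    rng = np.random.default_rng([design.seed, 1])

    n_g = design.n_genotypes
    n_m = len(mids)
    classes = [DEFAULT_CLASSES[i % len(DEFAULT_CLASSES)] for i in range(design.n_classes)]
    met_class = [classes[i % design.n_classes] for i in range(n_m)]
    class_sd = {c: rng.uniform(0.2, 0.6) for c in classes}

    mu = rng.normal(5.0, 1.0, size=n_m)
    sd = np.array([class_sd[c] for c in met_class])
    log_vals = rng.normal(mu[None, :], sd[None, :], size=(n_g, n_m))

    origins = np.array(design.origins)
    for m, shift in truth.origin_shifted.items():
        j = mids.index(m)
        log_vals[origins == "A", j] += shift

    vals = 10.0 ** log_vals
    if design.zero_inflation > 0:
        mask = rng.random(size=vals.shape) < design.zero_inflation
        vals[mask] = 0.0

    weights = rng.uniform(0.2, 2.0, size=n_g)
    values = pd.DataFrame(vals, index=design.genotype_ids, columns=mids)
    gmeta = pd.DataFrame(
        {"origin": design.origins, "root_dry_weight": weights},
        index=design.genotype_ids,
    )
    mmeta = pd.DataFrame({"chemical_class": met_class}, index=mids)
    mmeta["annotation_level"] = [2] * design.n_metabolites + [4] * design.n_unannotated_features
    return AbundanceMatrix(values, gmeta, mmeta)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def standardized_log_abundance(abundance: AbundanceMatrix) -> pd.DataFrame:
    """Column-standardized log10(x + 1) abundances (constant columns -> 0)."""
    logv = np.log10(abundance.values + 1.0)
    sd = logv.std(axis=0, ddof=0).replace(0.0, np.nan)
    z = (logv - logv.mean(axis=0)) / sd
    return z.fillna(0.0)


def simulate_inhibition(
    abundance: AbundanceMatrix,
    truth: PlantedTruth,
    design: StudyDesign,
) -> InhibitionMatrix:
    """Generate replicate-level AOI% from abundances and planted truth."""
    _check_truth_ids(truth, abundance.metabolites)
    rng = np.random.default_rng([design.seed, 2])
    z = standardized_log_abundance(abundance)
    sig = _logistic(z.values)
    col = {m: j for j, m in enumerate(abundance.metabolites)}
    genotypes = abundance.genotypes

    rows = []
    for s in design.strains:
        mean = np.zeros(len(genotypes))
        for m, w in truth.active_sets.get(s, {}).items():
            mean += w * sig[:, col[m]]
        if truth.synergy_triplet is not None and truth.synergy_weight != 0.0:
            prod = np.ones(len(genotypes))
            for m in truth.synergy_triplet:
                prod *= sig[:, col[m]]
            mean += truth.synergy_weight * prod
        for m, w in truth.stimulators.items():
            mean += w * sig[:, col[m]]
        for r in range(design.n_replicates):
            eps = (
                rng.normal(0.0, truth.noise_sd, size=len(genotypes))
                if truth.noise_sd > 0
                else np.zeros(len(genotypes))
            )
            aoi = np.clip(mean + eps, -40.0, 100.0)
            for g, v in zip(genotypes, aoi):
                rows.append((g, s, r + 1, v))

    reps = pd.DataFrame(rows, columns=["genotype", "strain", "replicate", "aoi"])
    smeta = pd.DataFrame({"domain": list(design.strains.values())},
                         index=list(design.strains))
    smeta.index.name = "strain"
    return InhibitionMatrix(reps, smeta)


def simulate_doseresponse(
    ec50: float,
    hill: float = 1.0,
    top: float = 10.0,
    n_conc: int = 8,
    noise_cv: float = 0.05,
    kinetics: str = "sigmoidal",
    timepoints=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    n_replicates: int = 3,
    span_decades: float = 1.5,
    seed: int = 0,
    inhibitor_id: str = "inhibitor",
    strain_id: str = "strain",
) -> DoseResponseSeries:
    """Simulate nitrite accumulation under an inhibitor dose series.

    Nitrite accumulates linearly in time at a concentration-dependent rate.
    For ``sigmoidal`` kinetics the rate is ``top * (1 - c^h / (c^h + ec50^h))``
    (at c = ec50 activity is exactly half the control); for ``linear``
    kinetics the rate falls linearly, hitting 50% at ec50 and zero at
    2*ec50.  Concentrations are log-spaced around ec50 plus the c = 0
    control; readings carry multiplicative noise of the given CV.
    """
    if ec50 <= 0 or top <= 0:
        raise ValueError("ec50 and top must be positive")
    if kinetics not in ("sigmoidal", "linear"):
        raise ValueError("kinetics must be 'sigmoidal' or 'linear'")
    rng = np.random.default_rng(seed)
    concs = np.concatenate([
        [0.0],
        np.logspace(np.log10(ec50) - span_decades, np.log10(ec50) + span_decades, n_conc),
    ])
    rows = []
    for c in concs:
        if kinetics == "sigmoidal":
            frac = 1.0 if c == 0 else 1.0 - c**hill / (c**hill + ec50**hill)
        else:
            frac = max(0.0, 1.0 - c / (2.0 * ec50))
        rate = top * frac
        for t in timepoints:
            for r in range(n_replicates):
                noise = 1.0 + noise_cv * rng.standard_normal() if noise_cv > 0 else 1.0
                rows.append((c, t, r + 1, max(0.0, rate * t * noise)))
    readings = pd.DataFrame(rows, columns=["concentration", "timepoint", "replicate", "nitrite"])
    return DoseResponseSeries(inhibitor_id, strain_id, readings,
                              meta={"ec50": ec50, "hill": hill, "top": top, "kinetics": kinetics})


def make_study(design: StudyDesign | None = None, truth: PlantedTruth | None = None) -> SyntheticStudy:
    """Generate a full synthetic study (abundances + inhibition + truth)."""
    design = design or StudyDesign()
    truth = truth or default_truth(design)
    abundance = simulate_abundances(design, truth)
    inhibition = simulate_inhibition(abundance, truth, design)
    return SyntheticStudy(abundance, inhibition, truth, design)
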