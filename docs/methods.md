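# Methods

This note documents the models, algorithmic choices and defaults of
`bniscreen`, and what the synthetic-data tests do and do not establish.

## Mass utilities

Monoisotopic masses (Da): C 12 (exact), H 1.00782503207, N 14.0030740048,
O 15.9949146196, P 30.97376163, S 31.97207100. Supported elements are
limited to CHNOPS; any other symbol is a parse error, never a silent zero.
Adduct m/z uses the **proton** mass 1.00727646688 Da (electron-corrected),
not the hydrogen-atom mass — this is what reproduces published 4-decimal
m/z values for [M+H]+ ions. `[M-H2O+H]+` subtracts one monoisotopic water
(18.01056468 Da). Display rounding is half-away-from-zero at 4 decimals.

Printed "mass accuracy (ppm)" columns in annotation tables derive from
unrounded instrument masses; recomputing ppm against the rounded printed
m/z routinely disagrees. `recompute_annotation_mz` therefore treats the
printed ppm as metadata and flags rows where |recomputed − printed| >
2 ppm, rather than asserting equality. One known annotation pathology — a
row whose printed formula is inconsistent with its printed water-loss m/z
by ~100 ppm — is detected by this flag; the intent of such rows is not
guessed.

## Synthetic studies

`StudyDesign` defaults state the emulated cohort: 44 genotypes split 20/24
into origins "A"/"B", 357 annotated metabolites in 12 chemical classes,
strains NF, NV (archaeal) and NM, NU (bacterial), 3 assay replicates.
Abundances are log-normal: per-metabolite log10 mean ~ N(5, 1), per-class
log10 sd ~ U[0.2, 0.6]; 10% of entries are zeroed to emulate "feature not
detected" (exact zeros, so presence/absence logic is exercisable); root
dry weights ~ U[0.2, 2.0] g.

Inhibition is

```
AOI%(g, s) = clip( Σ_{m∈active_s} w_m σ(z_gm)
                   + w_syn Π_{m∈triplet} σ(z_gm)
                   + Σ_{m∈stim} w'_m σ(z_gm) + ε,  −40, 100 )
```

with z the column-standardized log10(x+1) abundance, σ the logistic
function, ε ~ N(0, noise_sd) per replicate. The upper clip (100) is
complete inhibition; the lower clip (−40) admits growth stimulation,
which real screens observe; no published numeric floor exists, so −40 is
a design choice. Synergy is **multiplicative** so triplet members can be
individually weak but jointly strong — exactly the signal the GA selector
must find; the default planted truth gives triplet members individual
weight 8 and joint weight 60, five additive inhibitors per strain at
weight 15, stimulators at −10, noise sd 5 AOI units.

What a green test on this generator establishes: the statistical
machinery recovers planted monotone/synergistic structure at realistic
noise. What it does not: anything about chromatographic artifacts,
batch effects, compositionality of real MS intensities, or the biology of
particular metabolites.

Dose–response series accumulate nitrite linearly in time at rate
`top · (1 − c^h/(c^h + ec50^h))` (sigmoidal mode; exactly half the
control rate at c = ec50) or a linearly declining rate hitting zero at
2·ec50 (linear mode), with multiplicative reading noise of given CV and
a c = 0 control.

## Assay quantification

* AOI% from a single timepoint: `(1 − mean(treated)/mean(control)) × 100`;
  replicate-level AOI uses each treated replicate against the control
  mean. Unit-invariant; negative values kept.
* Slope-based AOI (for linear/polynomial kinetics): per-dose least-squares
  slope of nitrite vs time, `AOI%_c = (1 − slope_c/slope_0) × 100`;
  requires ≥ 3 timepoints and a positive control slope.
* EC50: bounded four-parameter logistic on AOI vs log10 concentration
  (bottom ∈ [−40, 20], top ∈ [60, 110], hill ∈ [0.05, 10]), 3-point
  deterministic multi-start; the reported EC50 is where the fitted curve
  crosses 50%. If the data never approach 50% and the crossing would be
  an extrapolation beyond the tested doses, or the fit fails, a
  log-linear interpolation between 50%-bracketing doses is used; with no
  bracket either, "EC50 not estimable" is raised. Recovery on simulated
  series (hill ∈ {0.8, 1, 2}, CV 5%): median relative error ≈ 3%;
  noise-free < 10⁻⁹.
* Group statistics: Wilcoxon rank-sum for two groups (W = rank sum of the
  first-listed group, as published W statistics imply; Mann–Whitney U also
  reported; exact p for group sizes ≤ 10, tie-corrected normal otherwise),
  Kruskal–Wallis with tie correction for more, Dunn's pairwise z-tests on
  pooled ranks with Bonferroni adjustment, and a compact letter display
  computed as the maximal cliques of the non-significance graph (groups
  share a letter iff their adjusted p ≥ 0.05).
* Inhibition heat-map clustering: Euclidean distance, complete linkage by
  default (the published choice is unstated; configurable), ids sorted
  beforehand so leaf orders are deterministic.

## Association screening

Spearman ρ is computed as Pearson on average ranks; two-sided p from the
t approximation with df = n − 2 (for n ≤ 7 this tracks the exact
permutation mid-p within 0.02). Flags: positive if ρ ≥ 0.40 and p ≤ 0.05;
negative at strain-specific cutoffs (−0.45 for NF/NM, −0.40 for NV/NU —
published panel captions are internally inconsistent here, so the
first-stated value per panel is the default and all cutoffs are config).
No multiple-testing correction enters the flags (the screen combines an
effect-size cut with raw p); a Benjamini–Hochberg column is emitted for
transparency. Constant columns yield undefined ρ and are flagged `ns`
with a warning.

## PLS networks

Classical two-block NIPALS with deflation, both blocks standardized;
PLS1 for per-strain regression, PLS2 on a one-hot quartile block for
PLS-DA. Weight-vector signs are fixed by forcing the largest-magnitude
entry positive, making components reproducible. Default 2 components
(unstated in the source analyses; typical for these plots). Edge scores
are relevance-network similarities Σ_h cor(x_j, t_h)·cor(y_k, t_h) —
the correlation of each variable with the shared latent components —
thresholded at |score| ≥ cutoff (0.40/0.35/0.38/0.45 per strain, 0.40 for
the quartile network; all configurable). A raw-correlation backend would
be a one-line swap of the similarity matrix. Quartiles: genotypes ranked
by mean AOI% across strains, split into four near-equal groups (Q1
highest), ties broken by genotype id.

## GA + canonical-correlation selection

Fitness of a metabolite subset against one strain's AOI vector:

* **linear-cca** (default): for a single response the first canonical
  correlation equals the multiple correlation √R²; computed from
  precomputed Gram matrices, so one evaluation is a k×k solve. Used for
  all high-repetition runs.
* **dcca**: two fully-connected encoders (defaults: hidden 16-16, tanh,
  scalar latent) trained jointly by full-batch Adam (lr 10⁻², 300 epochs,
  covariance regularizer 10⁻⁴) to maximize the regularized squared
  correlation of their outputs; fitness is the absolute final correlation.
  Implemented in pure numpy with manual backprop; deterministic given the
  config seed. With linear activations it converges to the linear CCA
  value (verified within 0.02). The absolute value is used because the
  direction of the latent axes is arbitrary.

GA (defaults): individuals are triplets of distinct metabolites,
population 40, 30 generations, tournament selection of size 3, uniform
per-slot crossover with duplicate repair, per-slot mutation 0.10
(replacement by a random unused metabolite), elitism 2. Each repetition r
runs on the seeded stream [seed, r]; 200 repetitions by default (50 also
conventional). Only the single best triplet per repetition is counted, so
Σ_m f_m = 3 × repetitions exactly. Fitness values are memoized per sorted
subset (valid because both backends are deterministic for fixed data).
Two selection tiers are reported: f > 10 (`selected`) and f ≥ 5
(`highlighted`). The 80/20 stability check reruns the selector on five
random 80% genotype subsets and reports pairwise Spearman correlations of
the frequency vectors and mean top-5 overlap.

Known limitation, deliberately not papered over: with a deterministic
fitness on fixed data, GA repetitions differ only in their random streams,
not in the landscape, so on **pure-noise** data the repetitions partially
re-converge to the same spurious optima and the null frequency
distribution is *not* near-uniform (the top spurious metabolite can reach
f ≈ 0.7 × repetitions). Near-uniform null frequencies would require a
per-repetition stochastic fitness or selection pressure too weak to find
planted signals. Frequencies from this selector should therefore always
be read against an explicit permutation/null run on the same data, never
against a uniform expectation.

## Pipeline

One YAML-serializable config drives all stages; every tabular output is
TSV with a fixed column order and a header comment carrying the hash of
the scientific config (output paths excluded from the hash). Reruns with
identical config and seed are byte-identical. The consolidated report
lists, per strain, the Spearman-flagged, network-connected and
GA-highlighted metabolites and their intersection (metabolites supported
by ≥ 2 evidence streams).
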