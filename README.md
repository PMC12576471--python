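# bniscreen

Analysis toolkit for screening plant root exudates for **biological
nitrification inhibition (BNI)**: the suppression of soil ammonia
oxidation by metabolites that roots release into the rhizosphere.

The package is aimed at plant/soil scientists who combine two data sets
per genotype panel:

1. a **root-exudate metabolome** — a genotype × metabolite intensity table
   from GC–MS / LC–MS profiling, with an annotation sidecar (molecular
   formula, ion species, observed m/z, retention time, chemical class), and
2. a **fast-track inhibition bioassay** — nitrite production of
   ammonia-oxidizing bacteria (AOB) and archaea (AOA) reporter strains
   exposed to each exudate, quantified as the ammonia-oxidation-inhibition
   percentage

   AOI% = (1 − N_treated / N_control) × 100,

   with EC50 the concentration at which activity falls to half of the
   control (negative AOI% = growth stimulation, retained throughout).

It links the two with a ladder of association methods, from univariate to
combinatorial:

* **Spearman screening** — per metabolite and strain, rank correlation of
  abundance with mean AOI%, flagged at ρ ≥ 0.40 (positive) or
  strain-specific negative cutoffs (−0.45 / −0.40) with p ≤ 0.05;
* **PLS relevance networks** — NIPALS partial-least-squares regression of
  AOI% on the standardized metabolite matrix; edges connect metabolites to
  strains where the relevance score |Σ_h cor(x_j, t_h)·cor(y, t_h)|
  exceeds a per-strain cutoff (0.40/0.35/0.38/0.45), plus a PLS-DA variant
  on inhibition quartiles Q1 (strongest) … Q4 (weakest);
* **GA triplet selection with canonical-correlation fitness** — a genetic
  algorithm over 3-metabolite subsets whose fitness is the canonical
  correlation between the subset's abundances and a strain's AOI vector
  (closed-form linear CCA, or a small two-encoder deep-CCA network in pure
  numpy). Over many GA repetitions the members of each repetition's best
  triplet are counted; reproducibly high-frequency metabolites are the
  combinatorially informative ones. This is the tool that detects
  *synergistic* metabolite sets whose members are individually weak.

Because raw screening data of this kind are rarely public, the package
ships a first-class synthetic-data generator (`bniscreen.synthetic_data`)
that emulates the statistical structure of such a study — 44 genotypes in
two origin groups (20/24), 357 annotated metabolites in 12 chemical
classes, four reporter strains (AOA: NF, NV; AOB: NM, NU) — with planted
ground truth (additive inhibitors, a synergistic triplet, stimulators,
origin-shifted metabolites) so every stage is testable end to end.

## Worked example

```python
from bniscreen.massutil import parse_formula, ion_mz, ppm_error, round_mz
from bniscreen.synthetic_data import StudyDesign, default_truth, make_study
from bniscreen.assoc import spearman_screen
from bniscreen.gadcca import GAConfig, ga_select

# --- annotation QC: theoretical adduct m/z from the formula
f = parse_formula("C9H10O5")                 # syringic acid
theo = ion_mz(f, "[M+H]+")
print(round_mz(theo))                        # 199.0601
print(ppm_error(199.0601, theo))             # 0.00 ppm vs the observed ion

# --- a synthetic 44 x 357 study with a planted synergistic triplet
design = StudyDesign(seed=1)
study = make_study(design, default_truth(design))
print(study.truth.synergy_triplet)           # ('m80', 'm224', 'm352')

# --- univariate screen: only the individually-strong signals appear
ct = spearman_screen(study.abundance, study.inhibition)
print(ct.for_strain("NF").query("flag == 'positive'").head())
#                  rho   p_value      flag
# m224        0.448686  0.002252  positive

# --- combinatorial GA selection: triplet members surface by frequency
tbl = ga_select(study.abundance, study.inhibition.strain_vector("NF"),
                GAConfig(repetitions=50, seed=1), backend="linear-cca")
print(tbl.table.head(5)[["f", "mean_fitness", "highlighted"]])
#              f  mean_fitness  highlighted
# m224        29      0.716921         True
# m29         19      0.712933         True
# m336        16      0.718040         True
```

The Spearman screen sees only `m224` (one triplet member happens to carry
enough marginal signal); the GA frequency table ranks it first with
occurrence f = 29 of 50 repetitions at canonical correlation ≈ 0.72 —
frequency, not any single correlation, is the evidence for combinatorial
activity.

The same stages run from the shell via the `bni` CLI
(`bni simulate | preprocess | assay | correlate | gadcca | run | report | ec50`),
with `bni run --config cfg.yaml` executing the whole pipeline
reproducibly (byte-identical outputs for identical config + seed).

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the
theoretical [M+H]+ ion m/z of seven published metabolite annotations
(uric acid, schaftoside, isatin, caffeic acid, syringic acid, ABOA,
cyclo(proline-leucine)) from their molecular formulas — monoisotopic
element masses plus the proton mass, rounded to 4 decimals — and writes
them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the models, defaults and known limitations.
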