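import numpy as np
import pandas as pd
import pytest

from bniscreen.containers import AbundanceMatrix, InhibitionMatrix
from bniscreen.synthetic_data import (PlantedTruth, StudyDesign, default_truth,
                                      make_study)


@pytest.fixture(scope="session")
def small_study():
    """Default-truth synthetic study at reduced size (44 x 60)."""
    design = StudyDesign(n_genotypes=44, n_metabolites=60, seed=3)
    return make_study(design, default_truth(design))


@pytest.fixture(scope="session")
def noiseless_single_signal_study():
    """One planted inhibitor, zero noise: AOI is a monotone map of it."""
    design = StudyDesign(n_genotypes=20, origin_split=(10, 10),
                         n_metabolites=10, zero_inflation=0.0, seed=5)
    truth = PlantedTruth(active_sets={s: {"m1": 60.0} for s in design.strains},
                         noise_sd=0.0)
    return make_study(design, truth)


@pytest.fixture
def tiny_abundance():
    """Hand-sized abundance matrix for exact-arithmetic checks."""
    rng = np.random.default_rng(0)
    genos = [f"g{i}" for i in range(6)]
    mets = [f"m{i}" for i in range(4)]
    vals = pd.DataFrame(rng.uniform(1, 100, size=(6, 4)), index=genos, columns=mets)
    gmeta = pd.DataFrame({"origin": ["A"] * 3 + ["B"] * 3,
                          "root_dry_weight": np.linspace(0.5, 1.5, 6)}, index=genos)
    mmeta = pd.DataFrame({"chemical_class": ["x", "x", "y", "y"]}, index=mets)
    return AbundanceMatrix(vals, gmeta, mmeta)


@pytest.fixture
def simple_inhibition():
    rng = np.random.default_rng(1)
    rows = []
    for g in [f"g{i}" for i in range(8)]:
        for s in ["NF", "NV", "NM", "NU"]:
            base = rng.uniform(-10, 80)
            for r in (1, 2, 3):
                rows.append((g, s, r, min(100.0, base + rng.normal(0, 2))))
    reps = pd.DataFrame(rows, columns=["genotype", "strain", "replicate", "aoi"])
    smeta = pd.DataFrame({"domain": ["AOA", "AOA", "AOB", "AOB"]},
                         index=["NF", "NV", "NM", "NU"])
    return InhibitionMatrix(reps, smeta)
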