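"""Core tabular containers shared across the analysis stages.

Everything is a thin dataclass around pandas objects:

* :class:`AbundanceMatrix` — genotype x metabolite intensity table with
  genotype metadata (origin group, root dry weight) and a metabolite
  metadata table (chemical class, annotation link).
* :class:`InhibitionMatrix` — replicate-level ammonia-oxidation-inhibition
  percentages (AOI%) per genotype x strain, with mean/SEM accessors.
* :class:`DoseResponseSeries` — nitrite readings over concentration x
  timepoint x replicate for one inhibitor x strain combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "InhibitionMatrix", "DoseResponseSeries"]


@dataclass
class AbundanceMatrix:
    """Genotype x metabolite abundances plus metadata.

    ``values``: DataFrame, rows = genotype ids, columns = metabolite ids,
    non-negative intensities (zeros mean "not detected").
    ``genotype_meta``: DataFrame indexed by genotype with at least columns
    ``origin`` and ``root_dry_weight`` (grams).
    ``metabolite_meta``: DataFrame indexed by metabolite with at least a
    ``chemical_class`` column.
    """

    values: pd.DataFrame
    genotype_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("genotype and metabolite ids must be unique")
        if not self.values.index.equals(self.genotype_meta.index):
            self.genotype_meta = self.genotype_meta.reindex(self.values.index)
            if self.genotype_meta.isna().all(axis=1).any():
                raise ValueError("genotype_meta missing rows for some genotypes")
        missing = self.values.columns.difference(self.metabolite_meta.index)
        if len(missing):
            raise ValueError(f"metabolite_meta missing rows for: {list(missing)[:5]}")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def copy_with(self, values: pd.DataFrame) -> "AbundanceMatrix":
        return AbundanceMatrix(values, self.genotype_meta.copy(), self.metabolite_meta.copy())

    def write(self, values_path, genotype_meta_path, metabolite_meta_path, sep: str = "\t") -> None:
        self.values.to_csv(values_path, sep=sep, index_label="genotype")
        self.genotype_meta.to_csv(genotype_meta_path, sep=sep, index_label="genotype")
        self.metabolite_meta.to_csv(metabolite_meta_path, sep=sep, index_label="metabolite")

    @classmethod
    def read(cls, values_path, genotype_meta_path, metabolite_meta_path, sep: str = "\t"):
        vals = pd.read_csv(values_path, sep=sep, index_col="genotype")
        vals = vals.apply(pd.to_numeric, errors="coerce")
        bad = vals.index[vals.isna().any(axis=1)]
        if len(bad):
            raise ValueError(
                f"abundance file has missing/non-numeric values in rows: {list(bad)[:5]}")
        gmeta = pd.read_csv(genotype_meta_path, sep=sep, index_col="genotype")
        mmeta = pd.read_csv(metabolite_meta_path, sep=sep, index_col="metabolite")
        return cls(vals, gmeta, mmeta)


@dataclass
class InhibitionMatrix:
    """Replicate-level AOI% per genotype x strain.

    ``replicates``: long DataFrame with columns
    ``genotype, strain, replicate, aoi``.  AOI% may be negative (growth
    stimulation) and is bounded above by 100 (complete inhibition).
    """

    replicates: pd.DataFrame
    strain_meta: pd.DataFrame | None = None  # index strain, column 'domain'

    def __post_init__(self) -> None:
        required = {"genotype", "strain", "replicate", "aoi"}
        if not required.issubset(self.replicates.columns):
            raise ValueError(f"replicates must have columns {sorted(required)}")
        if (self.replicates["aoi"] > 100 + 1e-9).any():
            raise ValueError("AOI% cannot exceed 100 (complete inhibition)")

    @property
    def strains(self) -> list[str]:
        return list(pd.unique(self.replicates["strain"]))

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.replicates["genotype"]))

    def mean_matrix(self) -> pd.DataFrame:
        """Genotype x strain matrix of replicate means."""
        return (
            self.replicates.pivot_table(index="genotype", columns="strain",
                                        values="aoi", aggfunc="mean")
            .rename_axis(index="genotype", columns="strain")
        )

    def sem_matrix(self) -> pd.DataFrame:
        return self.replicates.pivot_table(
            index="genotype", columns="strain", values="aoi",
            aggfunc=lambda x: np.std(x, ddof=1) / np.sqrt(len(x)),
        )

    def strain_vector(self, strain: str) -> pd.Series:
        """Mean AOI% per genotype for one strain."""
        m = self.mean_matrix()
        if strain not in m.columns:
            raise KeyError(f"unknown strain {strain!r}; have {list(m.columns)}")
        return m[strain]

    def write(self, path, sep: str = "\t") -> None:
        self.replicates.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep: str = "\t", strain_meta: pd.DataFrame | None = None):
        return cls(pd.read_csv(path, sep=sep), strain_meta)


@dataclass
class DoseResponseSeries:
    """Nitrite readings for one inhibitor on one strain.

    ``readings``: long DataFrame with columns
    ``concentration, timepoint, replicate, nitrite``.  Concentration 0 is
    the untreated control and must be present with >= 2 replicates.
    """

    inhibitor_id: str
    strain_id: str
    readings: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"concentration", "timepoint", "replicate", "nitrite"}
        if not req.issubset(self.readings.columns):
            raise ValueError(f"readings must have columns {sorted(req)}")
        if (self.readings["nitrite"] < 0).any():
            raise ValueError("nitrite readings must be non-negative")
        ctrl = self.readings[self.readings["concentration"] == 0]
        if ctrl.empty:
            raise ValueError("control (concentration 0) readings required")
        n_ctrl_reps = ctrl.groupby("timepoint")["replicate"].nunique().min()
        if n_ctrl_reps < 2:
            raise ValueError("controls need >= 2 replicates")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.readings["concentration"].unique())

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.readings["timepoint"].unique())
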