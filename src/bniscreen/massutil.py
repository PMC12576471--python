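"""Molecular-formula parsing, monoisotopic masses and adduct ion m/z.

High-resolution LC-MS annotation tables report, for each metabolite, the
molecular formula, the ion species measured (e.g. the protonated molecule
``[M+H]+`` or the in-source water-loss adduct ``[M-H2O+H]+``), the observed
m/z and a mass accuracy in ppm.  This module recomputes theoretical ion m/z
from the formula and checks the printed values.

Only singly-charged positive-mode species over the CHNOPS elements are
supported; anything else raises rather than silently contributing zero mass.
The adduct offset uses the *proton* mass (electron-corrected), not the mass
of a hydrogen atom: this is what reproduces published 4-decimal m/z values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "Formula",
    "IonSpecies",
    "MetaboliteRecord",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "read_annotation_table",
    "recompute_annotation_mz",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER_MASS",
]

#: Monoisotopic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Mass of a proton (Da); the electron-corrected [M+H]+ adduct offset.
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of H2O (Da), used for the water-loss adduct.
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

# Hill order: C first, H second, then the rest alphabetically.
_HILL_ORDER = ["C", "H", "N", "O", "P", "S"]


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition over CHNOPS.

    ``element_counts`` maps element symbol to a strictly positive count;
    elements that are absent are simply not present in the mapping.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("empty formula: at least one atom required")
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(
                    f"unsupported element {el!r}; supported: "
                    + ", ".join(sorted(MONOISOTOPIC_MASS))
                )
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    @property
    def n_atoms(self) -> int:
        return sum(self.element_counts.values())

    def __str__(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class IonSpecies:
    """A charged adduct species: label, mass offset (Da) and charge."""

    label: str
    mass_delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ion charge must be nonzero")


#: Registry of supported ion species, keyed by canonical label.
ION_SPECIES: dict[str, IonSpecies] = {
    "[M+H]+": IonSpecies("[M+H]+", PROTON_MASS, +1),
    "[M-H2O+H]+": IonSpecies("[M-H2O+H]+", PROTON_MASS - WATER_MASS, +1),
}


def _canonical_ion_label(label: str) -> str:
    """Normalize unicode dashes/spaces/sub-markers in an ion-species label."""
    s = label.replace("‐", "-").replace("−", "-").replace("–", "-")
    s = s.replace("_", "").replace("^", "").replace(" ", "")
    return s


def get_ion_species(label: str) -> IonSpecies:
    key = _canonical_ion_label(label)
    if key not in ION_SPECIES:
        raise ValueError(
            f"unknown ion species {label!r}; supported: {sorted(ION_SPECIES)}"
        )
    return ION_SPECIES[key]


@dataclass
class MetaboliteRecord:
    """One annotation row: identity, formula, ion species and observed m/z."""

    name: str
    formula: Formula
    ion_species: IonSpecies
    observed_mz: float
    rt: float
    chemical_class: str = ""
    inchikey: str | None = None
    annotation_level: int = 2
    mass_accuracy_ppm: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observed_mz <= 0:
            raise ValueError("observed m/z must be positive")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.annotation_level not in (1, 2, 3, 4):
            raise ValueError("annotation level must be 1-4")


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a molecular-formula string such as ``"C5H4N4O3"``.

    Underscore subscript markers as they appear in publication tables
    (``"C_5_H_4_N_4_O_3_"``) are tolerated and stripped.
    """
    if text is None:
        raise FormulaError("empty formula string")
    cleaned = text.replace("_", "").replace(" ", "").strip()
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None or m.group(1) == "":
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unsupported element symbol {el!r} in formula {text!r}"
            )
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula(counts)


def format_formula(f: Formula) -> str:
    """Canonical Hill-order string (C, H, then alphabetical)."""
    parts = []
    for el in _HILL_ORDER:
        n = f[el]
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: Formula) -> float:
    """Neutral monoisotopic mass in Da."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.element_counts.items())


def ion_mz(f: Formula, ion: IonSpecies | str) -> float:
    """Theoretical m/z of the given adduct of the neutral formula."""
    if isinstance(ion, str):
        ion = get_ion_species(ion)
    return (monoisotopic_mass(f) + ion.mass_delta) / abs(ion.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass accuracy in ppm: (obs - theo) / theo * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def round_mz(mz: float, decimals: int = 4) -> float:
    """Round half away from zero, the display convention for m/z columns."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(mz) * factor + 0.5) / factor, mz)


# ---------------------------------------------------------------------------
# Annotation sidecar I/O

_SIDECAR_COLUMNS = [
    "name",
    "inchikey",
    "annotation_level",
    "formula",
    "chemical_class",
    "ion_species",
    "mz",
    "rt_min",
    "mass_accuracy_ppm",
]


def read_annotation_table(path, sep: str = None) -> pd.DataFrame:
    """Read an annotation sidecar CSV/TSV (columns of the standard schema)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in _SIDECAR_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return df


def recompute_annotation_mz(df: pd.DataFrame, flag_ppm: float = 2.0) -> pd.DataFrame:
    """Recompute theoretical m/z and ppm error for every annotation row.

    Adds columns ``theoretical_mz``, ``recomputed_ppm`` and ``ppm_flag``.
    ``ppm_flag`` is True where the recomputed ppm (against the printed
    observed m/z) differs from the printed mass-accuracy column by more than
    ``flag_ppm`` — printed ppm values stem from unrounded instrument masses
    and are treated as metadata, not recomputable ground truth.
    """
    out = df.copy()
    theo, ppm, flag = [], [], []
    for _, row in df.iterrows():
        f = parse_formula(str(row["formula"]))
        t = ion_mz(f, str(row["ion_species"]))
        p = ppm_error(float(row["mz"]), t)
        theo.append(t)
        ppm.append(p)
        printed = row.get("mass_accuracy_ppm")
        if printed is None or (isinstance(printed, float) and math.isnan(printed)):
            flag.append(False)
        else:
            flag.append(abs(p - float(printed)) > flag_ppm)
    out["theoretical_mz"] = theo
    out["recomputed_ppm"] = ppm
    out["ppm_flag"] = flag
    return out
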