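"""Derived traits: carbon content, size classes, prevalence filtering.

Carbon per cell follows the Menden-Deuer & Lessard allometries, which
account for the decrease of specific carbon content with cell size:

    general phytoplankton:  C [pg] = 0.216 * V^0.939
    diatoms:                C [pg] = 0.288 * V^0.811

with V the mean cell biovolume in µm³.  The two curves cross near
V ≈ 9.46 µm³; above it diatoms carry less carbon per unit biovolume
(vacuole-rich cells), below it more.

Size classes come in three systems: two Sieburth classifications on the
minimum and maximum individual length (pico 0.2–2 µm, nano 2–20 µm, micro
20–200 µm, meso 0.2–20 mm) and the Ignatiades classification on individual
biovolume (pico < 10 µm³, nano 10–1,000 µm³, micro 10³–10⁶ µm³, macro
> 10⁶ µm³).  All intervals are applied left-closed right-open, so a length
of exactly 20 µm is microphytoplankton and a biovolume of exactly 10⁶ µm³
is macroplankton.  Sieburth lengths outside 0.2 µm – 20 mm clamp to the
end classes and are flagged rather than rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import individual_biovolume
from .schema import Flag, TraitTable, _is_missing

__all__ = [
    "CarbonModel",
    "GENERAL_CARBON",
    "DIATOM_CARBON",
    "SizeClassSystem",
    "SIEBURTH",
    "IGNATIADES",
    "carbon_content",
    "sieburth_class",
    "ignatiades_class",
    "derive_traits",
    "filter_occurrences",
]


@dataclass(frozen=True)
class CarbonModel:
    """Allometric carbon-biovolume model C = coefficient * V^exponent."""

    coefficient: float
    exponent: float

    def __call__(self, biovolume: float) -> float:
        return self.coefficient * biovolume ** self.exponent


GENERAL_CARBON = CarbonModel(coefficient=0.216, exponent=0.939)
DIATOM_CARBON = CarbonModel(coefficient=0.288, exponent=0.811)


def carbon_content(biovolume: float, group: str) -> float:
    """Mean carbon content per cell (pg C) from cell biovolume (µm³).

    Diatoms use the diatom-specific model; every other group the general
    phytoplankton model.
    """
    if _is_missing(biovolume) or not math.isfinite(float(biovolume)) or float(biovolume) <= 0:
        raise ValueError(f"biovolume must be > 0, got {biovolume!r}")
    model = DIATOM_CARBON if group == "diatoms" else GENERAL_CARBON
    return model(float(biovolume))


@dataclass(frozen=True)
class SizeClassSystem:
    """Ordered size classes on a linear or volumetric metric.

    ``boundaries`` are the k internal thresholds, ``labels`` the k+1 class
    names; intervals are left-closed right-open.  ``domain``, when set,
    clamps out-of-range values to the end classes (flagged by the caller).
    """

    name: str
    metric: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more label than boundaries")

    def classify(self, value: float) -> tuple[str, bool]:
        """(class label, clamped?) for a positive metric value."""
        v = float(value)
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{self.metric} must be > 0, got {value!r}")
        clamped = False
        if self.domain is not None:
            lo, hi = self.domain
            if v < lo or v >= hi:
                clamped = True
        idx = int(np.searchsorted(self.boundaries, v, side="right"))
        return self.labels[idx], clamped


SIEBURTH = SizeClassSystem(
    name="sieburth",
    metric="length (µm)",
    boundaries=(2.0, 20.0, 200.0),
    labels=(
        "picophytoplankton",
        "nanophytoplankton",
        "microphytoplankton",
        "mesophytoplankton",
    ),
    domain=(0.2, 20_000.0),
)

IGNATIADES = SizeClassSystem(
    name="ignatiades",
    metric="biovolume (µm³)",
    boundaries=(10.0, 1_000.0, 1_000_000.0),
    labels=("picoplankton", "nanoplankton", "microplankton", "macroplankton"),
)


def sieburth_class(length: float) -> str:
    """Sieburth size class of an individual length in µm."""
    return SIEBURTH.classify(length)[0]


def ignatiades_class(biovolume: float) -> str:
    """Ignatiades size class of an individual biovolume in µm³."""
    return IGNATIADES.classify(biovolume)[0]


# ---------------------------------------------------------------------------
# Table-level derivation
# ---------------------------------------------------------------------------

_DERIVED = (
    "Individual_Biovolume",
    "Carbon_Content",
    "Sieburth_Class_Min_Length",
    "Sieburth_Class_Max_Length",
    "Ignatiades_Class",
)


def derive_traits(table: TraitTable) -> TraitTable:
    """Compute the derived trait columns of a table, row by row.

    Adds/overwrites individual biovolume (multiplicative in cells per
    individual for colonies and filaments), carbon content (from cell
    biovolume and group), both Sieburth classes (from min and max
    individual length) and the Ignatiades class (from individual
    biovolume, falling back to cell biovolume with a flag when the
    cells-per-individual count is missing).  Rows missing an input get a
    missing output plus a flag; input columns are untouched.  Idempotent.
    """
    out = table.copy()
    out.flags = [f for f in out.flags if f.column not in _DERIVED]
    df = out.df
    n = len(df)
    ind_bv = np.full(n, np.nan)
    carbon = np.full(n, np.nan)
    sie_min: list = [pd.NA] * n
    sie_max: list = [pd.NA] * n
    igna: list = [pd.NA] * n

    def flag(i, name, col, note):
        out.flags.append(Flag(row=i, taxon=name, column=col, note=note))

    for i, rec in enumerate(table.records()):
        name = rec.taxon_name
        cell_bv = rec.trait("Cell_Biovolume")
        life_form = rec.trait("Life_Form")
        cells = rec.trait("Cells_Per_Individual")

        # individual biovolume
        iv = None
        if cell_bv is None or life_form is None:
            flag(i, name, "Individual_Biovolume",
                 "missing input: Cell_Biovolume or Life_Form")
        else:
            iv = individual_biovolume(float(cell_bv), str(life_form), cells)
            if iv is None:
                flag(i, name, "Individual_Biovolume",
                     "missing input: Cells_Per_Individual for a multicellular life form")
            else:
                ind_bv[i] = iv

        # carbon content per cell
        if cell_bv is None:
            flag(i, name, "Carbon_Content", "missing input: Cell_Biovolume")
        else:
            carbon[i] = carbon_content(float(cell_bv), rec.group or "")

        # Sieburth classes on min/max individual length
        for col, trait, store in (
            ("Sieburth_Class_Min_Length", "Min_Individual_Length", sie_min),
            ("Sieburth_Class_Max_Length", "Max_Individual_Length", sie_max),
        ):
            v = rec.trait(trait)
            if v is None:
                flag(i, name, col, f"missing input: {trait}")
            else:
                label, clamped = SIEBURTH.classify(float(v))
                store[i] = label
                if clamped:
                    flag(i, name, col, f"{trait}={v} outside 0.2 µm - 20 mm, "
                                       f"clamped to {label}")

        # Ignatiades class on individual biovolume (cell-biovolume fallback)
        basis = iv
        if basis is None and cell_bv is not None:
            basis = float(cell_bv)
            flag(i, name, "Ignatiades_Class",
                 "individual biovolume unavailable; classified on cell biovolume")
        if basis is None:
            flag(i, name, "Ignatiades_Class", "missing input: biovolume")
        else:
            igna[i] = IGNATIADES.classify(basis)[0]

    df["Individual_Biovolume"] = ind_bv
    df["Carbon_Content"] = carbon
    df["Sieburth_Class_Min_Length"] = pd.array(sie_min, dtype=object)
    df["Sieburth_Class_Max_Length"] = pd.array(sie_max, dtype=object)
    df["Ignatiades_Class"] = pd.array(igna, dtype=object)
    return out


# ---------------------------------------------------------------------------
# Occurrence-prevalence filter
# ---------------------------------------------------------------------------

def filter_occurrences(
    occ: pd.DataFrame,
    min_samples: int = 15,
    strict: bool = True,
) -> tuple[list[str], list[str]]:
    """Partition taxa by sample prevalence in a presence/absence matrix.

    ``occ`` has taxa as rows and samples as columns with binary entries.
    A taxon is kept iff it occurs in more than ``min_samples`` samples
    (strictly greater, the list-cleaning convention); ``strict=False``
    switches to >=.  Returns (kept, dropped) taxon lists in row order.
    """
    if min_samples < 0:
        raise ValueError(f"min_samples must be >= 0, got {min_samples}")
    values = occ.to_numpy()
    if not np.isin(values[~pd.isna(values)], (0, 1)).all():
        raise ValueError("occurrence matrix must contain only 0/1 entries")
    counts = np.nansum(values.astype(float), axis=1)
    keep = counts > min_samples if strict else counts >= min_samples
    taxa = [str(t) for t in occ.index]
    kept = [t for t, k in zip(taxa, keep) if k]
    dropped = [t for t, k in zip(taxa, keep) if not k]
    return kept, dropped
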