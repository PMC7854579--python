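"""Dataset composition summaries (taxon tallies by group or life form)."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .schema import TraitTable

__all__ = [
    "CompositionSummary",
    "group_composition",
    "lifeform_composition",
]


def _round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up rounding, matching one-decimal display percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionSummary:
    """Per-category taxon counts and display percentages (one decimal)."""

    dimension: str  # "group" | "life_form"
    counts: dict[str, int]
    percentages: dict[str, float]
    n_taxa: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[c] for c in self.counts],
            }
        )


def _composition(table: TraitTable, column: str, dimension: str) -> CompositionSummary:
    if len(table) == 0:
        raise ValueError("composition of an empty table is undefined")
    if column not in table.df.columns:
        raise ValueError(f"table has no {column!r} column")
    values = table.df[column].dropna()
    if values.empty:
        raise ValueError(f"no non-missing {column!r} values to summarize")
    counts = values.value_counts()
    # descending count, category name as tie-break, for stable display order
    items = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    n = int(counts.sum())
    return CompositionSummary(
        dimension=dimension,
        counts={str(c): int(k) for c, k in items},
        percentages={str(c): _round_half_up(100.0 * k / n) for c, k in items},
        n_taxa=n,
    )


def group_composition(table: TraitTable) -> CompositionSummary:
    """Share of each phytoplankton group in the taxa list."""
    return _composition(table, "Group", "group")


def lifeform_composition(table: TraitTable) -> CompositionSummary:
    """Share of each primary life form (cell / colony / filament)."""
    return _composition(table, "Life_Form", "life_form")
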