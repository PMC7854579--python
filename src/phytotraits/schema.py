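"""Trait-table data model: schema registry, CSV dialect IO, taxa codes.

A trait table is a pandas DataFrame (one row per taxon) wrapped together
with the :class:`TraitSchema` that types its columns and a list of
provenance flags.  The canonical packaged schema carries 10
identity/taxonomy columns and exactly 53 trait variables of four kinds
(continuous, categorical, boolean, text); the CSV dialect defaults to
semicolon separation with ``#NA`` as the missing token.
"""

from __future__ import annotations

import io
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Dialect",
    "TraitDef",
    "TraitSchema",
    "TraitTable",
    "TaxonRecord",
    "Flag",
    "TraitTableError",
    "CellParseError",
    "GROUPS",
    "load_trait_table",
    "write_trait_table",
    "make_taxa_code",
    "filter_by_rank",
    "lowest_rank",
    "default_schema",
]

#: The nine phytoplankton groups used for stable, phylogeny-independent
#: clustering of the taxa list.
GROUPS: tuple[str, ...] = (
    "chlorophytes",
    "cyanobacteria",
    "diatoms",
    "chrysophytes",
    "xanthophytes",
    "dinophytes",
    "euglenophytes",
    "cryptophytes",
    "haptophytes",
)

KINDS = ("continuous", "categorical", "boolean", "text")

#: Taxonomy columns from highest to lowest rank, with their rank labels.
TAXONOMY_COLUMNS: tuple[tuple[str, str], ...] = (
    ("Phylum", "phylum"),
    ("Class", "class"),
    ("Order", "order"),
    ("Family", "family"),
    ("Genus", "genus"),
    ("Species", "species"),
    ("Infra_Species", "infra-species"),
)

#: rank label -> depth; genus and below are retained by the list cleaning.
RANK_DEPTH: dict[str, int] = {
    "phylum": 0,
    "class": 1,
    "order": 2,
    "family": 3,
    "genus": 4,
    "species": 5,
    "subspecies": 6,
    "variety": 6,
    "form": 6,
    "infra-species": 6,
}
_GENUS_DEPTH = RANK_DEPTH["genus"]


class TraitTableError(ValueError):
    """Schema or dialect violation in a trait table."""


class CellParseError(TraitTableError):
    """A cell could not be parsed to its declared trait kind."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


@dataclass(frozen=True)
class Dialect:
    """CSV dialect of a trait table file.

    Defaults match the deposited format: semicolon separator, ``#NA``
    missing token, dot decimal mark, UTF-8.
    """

    separator: str = ";"
    missing_token: str = "#NA"
    decimal_mark: str = "."
    encoding: str = "utf-8"

    def __post_init__(self) -> None:
        if self.separator == self.decimal_mark:
            raise TraitTableError("dialect separator must differ from decimal mark")
        if len(self.separator) != 1:
            raise TraitTableError("dialect separator must be a single character")


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class TraitDef:
    """One variable of the trait table.

    ``kind`` is one of continuous / categorical / boolean / text.  Boolean
    variables admit exactly {0, 1, missing}; categorical variables carry a
    closed non-empty vocabulary in ``allowed_values``.
    """

    name: str
    kind: str
    units: str = ""
    allowed_values: tuple[str, ...] | None = None
    required: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise TraitTableError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.allowed_values:
                raise TraitTableError(
                    f"categorical trait {self.name!r} needs a non-empty allowed_values set"
                )
            object.__setattr__(self, "allowed_values", tuple(self.allowed_values))
        elif self.kind == "boolean":
            object.__setattr__(self, "allowed_values", ("0", "1"))
        elif self.allowed_values is not None:
            raise TraitTableError(
                f"{self.kind} trait {self.name!r} must not declare allowed_values"
            )


class TraitSchema:
    """Registry of identity columns and trait variables plus an alias map."""

    def __init__(
        self,
        identity: Sequence[TraitDef],
        traits: Sequence[TraitDef],
        aliases: Mapping[str, str] | None = None,
    ):
        self.identity = tuple(identity)
        self.traits = tuple(traits)
        self.aliases = dict(aliases or {})
        names = [d.name for d in self.identity + self.traits]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TraitTableError(f"duplicate column names in schema: {sorted(dupes)}")
        self._by_name = {d.name: d for d in self.identity + self.traits}

    # -- introspection ------------------------------------------------------
    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.identity + self.traits)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.traits)

    @property
    def required_columns(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.identity + self.traits if d.required)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> TraitDef:
        return self._by_name[name]

    def get(self, name: str) -> TraitDef | None:
        return self._by_name.get(name)

    def resolve(self, header: str) -> str:
        """Map a file header to its canonical column name via the alias map."""
        return self.aliases.get(header, header)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dict(cls, spec: Mapping) -> "TraitSchema":
        def build(entries: Iterable[Mapping]) -> list[TraitDef]:
            defs = []
            for e in entries:
                allowed = e.get("allowed_values")
                defs.append(
                    TraitDef(
                        name=e["name"],
                        kind=e["kind"],
                        units=e.get("units", "") or "",
                        allowed_values=tuple(str(v) for v in allowed) if allowed else None,
                        required=bool(e.get("required", False)),
                    )
                )
            return defs

        return cls(
            identity=build(spec.get("identity", ())),
            traits=build(spec.get("traits", ())),
            aliases=spec.get("aliases") or {},
        )

    @classmethod
    def from_yaml(cls, path) -> "TraitSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def dump(defs: Sequence[TraitDef]) -> list[dict]:
            out = []
            for d in defs:
                e: dict = {"name": d.name, "kind": d.kind}
                if d.units:
                    e["units"] = d.units
                if d.kind == "categorical":
                    e["allowed_values"] = list(d.allowed_values)
                if d.required:
                    e["required"] = True
                out.append(e)
            return out

        return {
            "identity": dump(self.identity),
            "traits": dump(self.traits),
            "aliases": dict(self.aliases),
        }


_DEFAULT_SCHEMA: TraitSchema | None = None


def default_schema() -> TraitSchema:
    """The packaged canonical schema (10 identity columns, 53 traits)."""
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        text = resources.files("phytotraits.data").joinpath("schema.yaml").read_text("utf-8")
        _DEFAULT_SCHEMA = TraitSchema.from_dict(yaml.safe_load(text))
    return _DEFAULT_SCHEMA


@dataclass(frozen=True)
class Flag:
    """Provenance note attached to one cell of a trait table."""

    row: int
    taxon: str
    column: str
    note: str


class TraitTable:
    """A typed trait table: DataFrame + schema + cell-level flags."""

    def __init__(self, df: pd.DataFrame, schema: TraitSchema | None = None,
                 flags: Sequence[Flag] = ()):
        self.schema = schema or default_schema()
        self.df = df
        self.flags = list(flags)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "TraitTable":
        return TraitTable(self.df.copy(), self.schema, list(self.flags))

    def records(self) -> Iterable["TaxonRecord"]:
        for i, (_, row) in enumerate(self.df.iterrows()):
            yield TaxonRecord.from_row(i, row, self.schema)

    def record(self, i: int) -> "TaxonRecord":
        return TaxonRecord.from_row(i, self.df.iloc[i], self.schema)


def _is_missing(value) -> bool:
    return value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value))


@dataclass
class TaxonRecord:
    """Per-taxon view used by the consistency-rule engine."""

    index: int
    taxon_name: str
    taxa_code: str | None
    group: str | None
    taxonomy: dict[str, str]
    traits: dict[str, object]

    @classmethod
    def from_row(cls, index: int, row: pd.Series, schema: TraitSchema) -> "TaxonRecord":
        def val(col):
            if col not in row.index:
                return None
            v = row[col]
            return None if _is_missing(v) else v

        taxonomy = {}
        for col, rank in TAXONOMY_COLUMNS:
            v = val(col)
            if v is not None:
                taxonomy[rank] = str(v)
        traits = {}
        for name in schema.trait_names:
            traits[name] = val(name)
        return cls(
            index=index,
            taxon_name=str(val("Taxa_Name") or f"row {index}"),
            taxa_code=val("Taxa_Code"),
            group=val("Group"),
            taxonomy=taxonomy,
            traits=traits,
        )

    def trait(self, name: str):
        """Trait value, or None when missing."""
        return self.traits.get(name)


# ---------------------------------------------------------------------------
# CSV dialect IO
# ---------------------------------------------------------------------------

def _parse_column(raw: pd.Series, tdef: TraitDef, dialect: Dialect) -> pd.Series:
    missing = raw.isna()
    if tdef.kind == "continuous":
        text = raw.where(~missing, "0")
        if dialect.decimal_mark != ".":
            text = text.str.replace(dialect.decimal_mark, ".", regex=False)
        parsed = pd.to_numeric(text, errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellParseError(
                f"cell at row {i}, column {tdef.name!r}: {raw.iloc[i]!r} "
                f"is not a valid number",
                row=i, column=tdef.name,
            )
        return parsed.astype(float).where(~missing, np.nan)
    if tdef.kind == "boolean":
        vals = raw.where(~missing, "0").str.strip()
        bad = ~vals.isin(("0", "1")) & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellParseError(
                f"cell at row {i}, column {tdef.name!r}: {raw.iloc[i]!r} "
                f"is not a valid boolean (expected 0 or 1)",
                row=i, column=tdef.name,
            )
        out = vals.astype("int64").astype("Int64")
        return out.where(~missing, pd.NA)
    if tdef.kind == "categorical":
        vals = raw.where(missing, raw.str.strip())
        bad = ~vals.isin(tdef.allowed_values) & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CellParseError(
                f"cell at row {i}, column {tdef.name!r}: {raw.iloc[i]!r} "
                f"is not among the allowed values {tdef.allowed_values}",
                row=i, column=tdef.name,
            )
        return vals.where(~missing, pd.NA).astype(object)
    # text
    return raw.where(~missing, pd.NA).astype(object)


def load_trait_table(
    path_or_buf,
    dialect: Dialect = DEFAULT_DIALECT,
    schema: TraitSchema | None = None,
) -> TraitTable:
    """Read a trait-table CSV in the given dialect against a schema.

    Every cell is parsed to its declared kind; the missing token becomes an
    explicit missing value.  Columns unknown to the schema are preserved
    verbatim (as text) in their file positions.
    """
    schema = schema or default_schema()
    raw = pd.read_csv(
        path_or_buf,
        sep=dialect.separator,
        dtype=str,
        encoding=dialect.encoding,
        na_values=[dialect.missing_token],
        keep_default_na=False,
        skip_blank_lines=False,
    )
    raw.columns = [schema.resolve(c) for c in raw.columns]
    missing_req = [c for c in schema.required_columns if c not in raw.columns]
    if missing_req:
        raise TraitTableError(f"missing required column(s): {missing_req}")

    out = {}
    for col in raw.columns:
        tdef = schema.get(col)
        if tdef is None:  # passthrough column, kept verbatim
            out[col] = raw[col].where(~raw[col].isna(), pd.NA).astype(object)
        else:
            out[col] = _parse_column(raw[col], tdef, dialect)
    df = pd.DataFrame(out, columns=list(raw.columns))

    if "Taxa_Code" in df.columns:
        codes = df["Taxa_Code"].dropna()
        dup = codes[codes.duplicated()].unique().tolist()
        if dup:
            raise TraitTableError(f"duplicate taxa codes: {sorted(map(str, dup))}")
    return TraitTable(df, schema)


def _format_cell(value, tdef: TraitDef | None, dialect: Dialect) -> str:
    if _is_missing(value):
        return dialect.missing_token
    if tdef is not None and tdef.kind == "continuous":
        text = repr(float(value))
        if dialect.decimal_mark != ".":
            text = text.replace(".", dialect.decimal_mark)
        return text
    if tdef is not None and tdef.kind == "boolean":
        return str(int(value))
    return str(value)


def write_trait_table(table: TraitTable, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    """Write a trait table so that reading it back reproduces it exactly."""
    df, schema = table.df, table.schema
    lines = [dialect.separator.join(df.columns)]
    defs = [schema.get(c) for c in df.columns]
    for _, row in df.iterrows():
        cells = [_format_cell(v, d, dialect) for v, d in zip(row.to_numpy(), defs)]
        lines.append(dialect.separator.join(cells))
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w", encoding=dialect.encoding, newline="") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Taxa codes
# ---------------------------------------------------------------------------

_GENUS_ONLY_EPITHETS = {"sp", "spp", "spec", "species"}


def _letters(text: str) -> str:
    """ASCII letters only, diacritics stripped, uppercased."""
    norm = unicodedata.normalize("NFKD", text)
    return "".join(c for c in norm if c.isascii() and c.isalpha()).upper()


def make_taxa_code(
    genus: str,
    epithet: str | None = None,
    infra: str | None = None,
    *,
    species_part: str = "first3",
) -> str:
    """Six-letter taxon code: 3 genus letters + 3 species-part letters.

    The species part comes from the lowest-rank epithet (infra-specific
    denomination when present, else the species epithet); ``species_part``
    selects its first three (default) or last three letters.  Genus-only
    taxa (no epithet, or a placeholder like "sp.") get the filler ``SPX``.
    """
    if species_part not in ("first3", "last3"):
        raise ValueError(f"species_part must be 'first3' or 'last3', got {species_part!r}")
    g = _letters(genus or "")
    if len(g) < 3:
        raise ValueError(f"genus {genus!r} has fewer than 3 usable letters")
    part = None
    for candidate in (infra, epithet):
        if candidate is None:
            continue
        letters = _letters(candidate)
        if len(letters) >= 3 and letters.lower() not in _GENUS_ONLY_EPITHETS:
            part = letters
            break
    if part is None:
        tail = "SPX"
    else:
        tail = part[:3] if species_part == "first3" else part[-3:]
    return g[:3] + tail


def assign_taxa_codes(
    table: TraitTable,
    *,
    species_part: str = "first3",
    overrides: Mapping[str, str] | None = None,
) -> TraitTable:
    """Fill ``Taxa_Code`` from the taxonomy columns.

    Collisions between generated codes are errors; resolution is only via an
    explicit ``overrides`` map keyed by taxon name.
    """
    overrides = dict(overrides or {})
    out = table.copy()
    codes: list[str] = []
    seen: dict[str, str] = {}
    for rec in table.records():
        name = rec.taxon_name
        if name in overrides:
            code = overrides[name]
        else:
            code = make_taxa_code(
                rec.taxonomy.get("genus", ""),
                rec.taxonomy.get("species"),
                rec.taxonomy.get("infra-species"),
                species_part=species_part,
            )
        if code in seen and seen[code] != name:
            raise TraitTableError(
                f"taxa-code collision: {name!r} and {seen[code]!r} both map to "
                f"{code}; supply an override map to resolve"
            )
        seen[code] = name
        codes.append(code)
    out.df["Taxa_Code"] = codes
    return out


# ---------------------------------------------------------------------------
# Rank-based list cleaning
# ---------------------------------------------------------------------------

def lowest_rank(record: TaxonRecord) -> str:
    """Label of the lowest determined taxonomic rank of a record."""
    best = None
    for _, rank in TAXONOMY_COLUMNS:
        if rank in record.taxonomy:
            best = rank
    if best is None:
        raise TraitTableError(f"record {record.taxon_name!r} carries no taxonomy")
    return best


def filter_by_rank(
    table: TraitTable,
    ranks: Sequence[str] | None = None,
) -> tuple[TraitTable, TraitTable]:
    """Partition a table into (kept, rejected) by determination rank.

    Taxa determined to genus rank or below (species, variety, form, ...)
    are kept; higher-rank determinations (order, class, phylum) are
    rejected.  ``ranks`` optionally supplies one explicit rank label per
    row instead of inferring from the taxonomy columns.
    """
    if ranks is not None and len(ranks) != len(table):
        raise TraitTableError("ranks must supply one label per record")
    keep_mask = []
    for i, rec in enumerate(table.records()):
        label = str(ranks[i]).lower() if ranks is not None else lowest_rank(rec)
        if label not in RANK_DEPTH:
            raise TraitTableError(
                f"unknown rank label {label!r} (known: {sorted(RANK_DEPTH)})"
            )
        keep_mask.append(RANK_DEPTH[label] >= _GENUS_DEPTH)
    mask = np.asarray(keep_mask, dtype=bool)
    kept = TraitTable(table.df.loc[mask].reset_index(drop=True), table.schema)
    rejected = TraitTable(table.df.loc[~mask].reset_index(drop=True), table.schema)
    return kept, rejected
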