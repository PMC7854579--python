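"""Schema registry, CSV dialect IO, taxa codes and rank cleaning."""

import io

import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phytotraits as pt
from phytotraits.schema import (
    Dialect,
    TraitDef,
    TraitTableError,
    filter_by_rank,
    load_trait_table,
    make_taxa_code,
    write_trait_table,
)

from conftest import random_cells_table


class TestTraitDef:
    def test_boolean_kind_admits_exactly_zero_and_one(self):
        d = TraitDef("X", "boolean")
        assert d.allowed_values == ("0", "1")

    def test_categorical_requires_vocabulary(self):
        with pytest.raises(TraitTableError):
            TraitDef("X", "categorical")

    def test_unknown_kind_rejected(self):
        with pytest.raises(TraitTableError):
            TraitDef("X", "integer")

    def test_schema_rejects_duplicate_names(self):
        with pytest.raises(TraitTableError, match="duplicate"):
            pt.TraitSchema([], [TraitDef("A", "text"), TraitDef("A", "text")])


class TestDefaultSchema:
    def test_registry_holds_53_traits(self):
        assert len(pt.default_schema().traits) == 53

    def test_trait_kinds_cover_all_four(self):
        kinds = {d.kind for d in pt.default_schema().traits}
        assert kinds == {"continuous", "categorical", "boolean", "text"}

    def test_alias_map_resolves_to_canonical_headers(self):
        s = pt.default_schema()
        assert s.resolve("Life_form") == "Life_Form"
        assert s.resolve("Life_Form") == "Life_Form"

    def test_yaml_dict_round_trip(self):
        s = pt.default_schema()
        s2 = pt.TraitSchema.from_dict(s.to_dict())
        assert s2.trait_names == s.trait_names
        assert s2["Group"].allowed_values == s["Group"].allowed_values


class TestDialect:
    def test_separator_must_differ_from_decimal_mark(self):
        with pytest.raises(TraitTableError):
            Dialect(separator=".", decimal_mark=".")


class TestLoadTraitTable:
    def test_missing_token_becomes_missing_value(self, small_table):
        df = small_table.df.copy()
        df.at[1, "Cell_Biovolume"] = float("nan")
        buf = io.StringIO()
        write_trait_table(pt.TraitTable(df, small_table.schema), buf)
        assert ";#NA;" in buf.getvalue().splitlines()[2]
        loaded = load_trait_table(io.StringIO(buf.getvalue()))
        assert pd.isna(loaded.df.at[1, "Cell_Biovolume"])

    def test_bad_boolean_cell_names_row_and_column(self, small_table):
        buf = io.StringIO()
        write_trait_table(small_table, buf)
        text = buf.getvalue().replace(";1;", ";2;", 1)
        with pytest.raises(TraitTableError, match=r"row \d+, column"):
            load_trait_table(io.StringIO(text))

    def test_duplicate_taxa_code_rejected(self, small_table):
        df = small_table.df.copy()
        df["Taxa_Code"] = df["Taxa_Code"].iloc[0]
        buf = io.StringIO()
        write_trait_table(pt.TraitTable(df, small_table.schema), buf)
        with pytest.raises(TraitTableError, match="duplicate taxa codes"):
            load_trait_table(io.StringIO(buf.getvalue()))

    def test_missing_required_column_rejected(self):
        with pytest.raises(TraitTableError, match="required"):
            load_trait_table(io.StringIO("A;B\n1;2\n"))

    def test_unknown_columns_pass_through_verbatim(self, small_table):
        df = small_table.df.copy()
        df["Source_Reference"] = "Komarek 1999"
        buf = io.StringIO()
        write_trait_table(pt.TraitTable(df, small_table.schema), buf)
        loaded = load_trait_table(io.StringIO(buf.getvalue()))
        assert list(loaded.df["Source_Reference"]) == ["Komarek 1999"] * len(df)

    def test_empty_table_round_trips_to_zero_rows(self):
        schema = pt.default_schema()
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in schema.columns})
        buf = io.StringIO()
        write_trait_table(pt.TraitTable(df, schema), buf)
        loaded = load_trait_table(io.StringIO(buf.getvalue()))
        assert len(loaded) == 0
        assert list(loaded.df.columns) == list(schema.columns)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_identity_random_tables(self, seed):
        import numpy as np

        table = random_cells_table(np.random.default_rng(seed), n_rows=6)
        buf = io.StringIO()
        write_trait_table(table, buf)
        loaded = load_trait_table(io.StringIO(buf.getvalue()))
        pdt.assert_frame_equal(table.df, loaded.df)

    def test_round_trip_with_french_decimal_mark(self, small_table):
        dialect = Dialect(separator=";", decimal_mark=",")
        buf = io.StringIO()
        write_trait_table(small_table, buf, dialect=dialect)
        loaded = load_trait_table(io.StringIO(buf.getvalue()), dialect=dialect)
        pdt.assert_frame_equal(small_table.df, loaded.df)


class TestTaxaCode:
    @pytest.mark.parametrize(
        "genus,epithet,infra,expected",
        [
            ("Microcystis", "aeruginosa", None, "MICAER"),
            ("Ceratium", None, None, "CERSPX"),
            ("Navicula", "sp.", None, "NAVSPX"),
            ("Anabaena", "flos-aquae", None, "ANAFLO"),
            ("Cosmarium", "depressum", "planctonicum", "COSPLA"),
        ],
    )
    def test_printed_rule_with_fillers(self, genus, epithet, infra, expected):
        assert make_taxa_code(genus, epithet, infra) == expected

    def test_last3_variant_uses_epithet_tail(self):
        assert make_taxa_code("Microcystis", "aeruginosa", species_part="last3") == "MICOSA"

    def test_diacritics_stripped(self):
        assert make_taxa_code("Képhyrion", "spirale") == "KEPSPI"

    def test_short_genus_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            make_taxa_code("Ab", "minor")

    @given(
        genus=st.text(alphabet=st.characters(categories=["Lu", "Ll"]), min_size=3, max_size=12),
        epithet=st.one_of(
            st.none(),
            st.text(alphabet=st.characters(categories=["Lu", "Ll"]), min_size=0, max_size=12),
        ),
    )
    @settings(max_examples=200, derandomize=True)
    def test_code_is_six_uppercase_ascii_letters_and_idempotent(self, genus, epithet):
        try:
            code = make_taxa_code(genus, epithet)
        except ValueError:
            return  # genus with < 3 usable ASCII letters
        assert len(code) == 6
        assert code.isalpha() and code.isascii() and code.isupper()
        assert make_taxa_code(genus, epithet) == code


class TestFilterByRank:
    def test_partition_preserves_order_and_loses_nothing(self, small_table):
        ranks = ["order" if i % 3 == 0 else "species" for i in range(len(small_table))]
        kept, rejected = filter_by_rank(small_table, ranks=ranks)
        assert len(kept) + len(rejected) == len(small_table)
        names = set(small_table.df["Taxa_Name"])
        assert set(kept.df["Taxa_Name"]) | set(rejected.df["Taxa_Name"]) == names
        assert list(kept.df["Taxa_Name"]) == [
            n for n, r in zip(small_table.df["Taxa_Name"], ranks) if r == "species"
        ]

    @pytest.mark.parametrize(
        "rank,kept_expected",
        [("order", False), ("class", False), ("phylum", False),
         ("genus", True), ("species", True), ("variety", True), ("form", True)],
    )
    def test_genus_and_below_conserved(self, small_table, rank, kept_expected):
        ranks = [rank] * len(small_table)
        kept, rejected = filter_by_rank(small_table, ranks=ranks)
        assert (len(kept) == len(small_table)) is kept_expected

    def test_rank_inferred_from_taxonomy_columns(self, small_table):
        df = small_table.df.copy()
        # blank everything below order for the first record
        for col in ("Family", "Genus", "Species", "Infra_Species"):
            df.at[0, col] = pd.NA
        kept, rejected = filter_by_rank(pt.TraitTable(df, small_table.schema))
        assert len(rejected) == 1
        assert rejected.df.at[0, "Taxa_Name"] == df.at[0, "Taxa_Name"]

    def test_unknown_rank_label_is_an_error(self, small_table):
        with pytest.raises(TraitTableError, match="tribe"):
            filter_by_rank(small_table, ranks=["tribe"] * len(small_table))

    def test_empty_table_yields_empty_partition(self):
        schema = pt.default_schema()
        empty = pt.TraitTable(
            pd.DataFrame({c: pd.Series(dtype=object) for c in schema.columns}), schema
        )
        kept, rejected = filter_by_rank(empty)
        assert len(kept) == 0 and len(rejected) == 0
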