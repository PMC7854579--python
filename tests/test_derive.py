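"""Carbon model, size classifiers, table derivation, occurrence filter."""

import math

import numpy as np
import pandas as pd
import pytest

import phytotraits as pt
from phytotraits.derive import (
    IGNATIADES,
    SIEBURTH,
    carbon_content,
    derive_traits,
    filter_occurrences,
    ignatiades_class,
    sieburth_class,
)


class TestCarbonModel:
    def test_unit_biovolume_recovers_model_coefficients(self):
        assert carbon_content(1.0, "chlorophytes") == 0.216
        assert carbon_content(1.0, "diatoms") == 0.288

    def test_general_model_evaluation(self):
        assert carbon_content(1000.0, "chlorophytes") == pytest.approx(
            0.216 * 1000**0.939
        )
        assert carbon_content(1000.0, "chlorophytes") == pytest.approx(141.7, abs=0.05)

    @pytest.mark.parametrize(
        "group", ["cyanobacteria", "cryptophytes", "haptophytes", "euglenophytes"]
    )
    def test_every_non_diatom_group_uses_general_model(self, group):
        assert carbon_content(50.0, group) == pytest.approx(0.216 * 50**0.939)

    def test_strictly_increasing_in_biovolume(self):
        grid = np.logspace(-2, 8, 60)
        for group in ("chlorophytes", "diatoms"):
            vals = [carbon_content(v, group) for v in grid]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_curves_cross_near_nine_and_a_half(self):
        # 0.216 V^0.939 = 0.288 V^0.811  =>  V = (4/3)^(1/0.128) ~ 9.46
        crossing = (0.288 / 0.216) ** (1 / (0.939 - 0.811))
        assert crossing == pytest.approx(9.47, abs=0.05)
        below, above = crossing * 0.9, crossing * 1.1
        assert carbon_content(below, "diatoms") > carbon_content(below, "chlorophytes")
        assert carbon_content(above, "diatoms") < carbon_content(above, "chlorophytes")

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_nonpositive_biovolume_is_an_error(self, bad):
        with pytest.raises(ValueError):
            carbon_content(bad, "diatoms")


class TestSizeClassifiers:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (1.0, "picophytoplankton"),
            (1.999, "picophytoplankton"),
            (2.0, "nanophytoplankton"),
            (19.99, "nanophytoplankton"),
            (20.0, "microphytoplankton"),
            (50.0, "microphytoplankton"),
            (199.9, "microphytoplankton"),
            (200.0, "mesophytoplankton"),
            (19_999.0, "mesophytoplankton"),
        ],
    )
    def test_sieburth_thresholds_left_closed(self, length, expected):
        assert sieburth_class(length) == expected

    @pytest.mark.parametrize(
        "bv,expected",
        [
            (5.0, "picoplankton"),
            (9.999, "picoplankton"),
            (10.0, "nanoplankton"),
            (999.0, "nanoplankton"),
            (1_000.0, "microplankton"),
            (5_000.0, "microplankton"),
            (999_999.0, "microplankton"),
            (1_000_000.0, "macroplankton"),
            (1e9, "macroplankton"),
        ],
    )
    def test_ignatiades_thresholds_left_closed(self, bv, expected):
        assert ignatiades_class(bv) == expected

    def test_out_of_range_lengths_clamp_with_flag(self):
        label, clamped = SIEBURTH.classify(0.05)
        assert (label, clamped) == ("picophytoplankton", True)
        label, clamped = SIEBURTH.classify(50_000.0)
        assert (label, clamped) == ("mesophytoplankton", True)
        assert SIEBURTH.classify(5.0) == ("nanophytoplankton", False)

    def test_classifiers_partition_their_domain(self):
        rng = np.random.default_rng(1)
        for v in np.exp(rng.uniform(np.log(1e-2), np.log(1e9), 500)):
            assert ignatiades_class(v) in IGNATIADES.labels
        for v in np.exp(rng.uniform(np.log(0.2), np.log(2e4), 500)):
            assert sieburth_class(v) in SIEBURTH.labels

    @pytest.mark.parametrize("classify", [sieburth_class, ignatiades_class])
    def test_nonpositive_inputs_rejected(self, classify):
        with pytest.raises(ValueError):
            classify(0.0)
        with pytest.raises(ValueError):
            classify(-4.0)


class TestDeriveTraits:
    def test_unit_biovolume_diatom_row_gets_diatom_carbon(self, valid_table):
        df = valid_table.df.copy()
        idx = df.index[df["Group"] == "diatoms"][0]
        df.at[idx, "Cell_Biovolume"] = 1.0
        out = derive_traits(pt.TraitTable(df, valid_table.schema))
        assert out.df.at[idx, "Carbon_Content"] == 0.288

    def test_each_derived_cell_matches_scalar_recomputation(self, valid_table):
        out = derive_traits(valid_table)
        for rec in out.records():
            cell_bv = rec.trait("Cell_Biovolume")
            assert rec.trait("Carbon_Content") == pytest.approx(
                carbon_content(cell_bv, rec.group)
            )
            expected_iv = pt.individual_biovolume(
                cell_bv, rec.trait("Life_Form"), rec.trait("Cells_Per_Individual")
            )
            assert rec.trait("Individual_Biovolume") == pytest.approx(expected_iv)
            assert rec.trait("Sieburth_Class_Min_Length") == sieburth_class(
                rec.trait("Min_Individual_Length")
            )
            assert rec.trait("Sieburth_Class_Max_Length") == sieburth_class(
                rec.trait("Max_Individual_Length")
            )
            assert rec.trait("Ignatiades_Class") == ignatiades_class(expected_iv)

    def test_missing_inputs_give_missing_outputs_plus_flags(self, small_table):
        df = small_table.df.copy()
        df.at[0, "Max_Individual_Length"] = np.nan
        out = derive_traits(pt.TraitTable(df, small_table.schema))
        assert pd.isna(out.df.at[0, "Sieburth_Class_Max_Length"])
        assert any(
            f.row == 0 and f.column == "Sieburth_Class_Max_Length" for f in out.flags
        )

    def test_missing_cell_count_falls_back_to_cell_biovolume(self, small_table):
        df = small_table.df.copy()
        idx = df.index[df["Life_Form"] != "cell"][0]
        df.at[idx, "Cells_Per_Individual"] = np.nan
        out = derive_traits(pt.TraitTable(df, small_table.schema))
        assert pd.isna(out.df.at[idx, "Individual_Biovolume"])
        assert out.df.at[idx, "Ignatiades_Class"] == ignatiades_class(
            df.at[idx, "Cell_Biovolume"]
        )
        notes = [f.note for f in out.flags if f.row == idx]
        assert any("cell biovolume" in n for n in notes)

    def test_idempotent(self, small_table):
        once = derive_traits(small_table)
        twice = derive_traits(once)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert len(once.flags) == len(twice.flags)

    def test_input_columns_untouched(self, small_table):
        out = derive_traits(small_table)
        inputs = [
            c for c in small_table.df.columns
            if c not in (
                "Individual_Biovolume", "Carbon_Content", "Sieburth_Class_Min_Length",
                "Sieburth_Class_Max_Length", "Ignatiades_Class",
            )
        ]
        pd.testing.assert_frame_equal(out.df[inputs], small_table.df[inputs])


class TestFilterOccurrences:
    def exact_count_matrix(self):
        # taxon_k occurs in exactly k samples, k = 0..30
        taxa = [f"taxon_{k:02d}" for k in range(31)]
        mat = np.zeros((31, 40), dtype=int)
        for k in range(31):
            mat[k, :k] = 1
        return pd.DataFrame(mat, index=taxa)

    def test_strictly_more_than_fifteen(self):
        occ = self.exact_count_matrix()
        kept, dropped = filter_occurrences(occ, min_samples=15)
        assert "taxon_15" in dropped
        assert "taxon_16" in kept
        assert kept == [f"taxon_{k:02d}" for k in range(16, 31)]

    def test_kept_set_equals_brute_force_recount(self):
        occ = pt.generate_occurrences(
            [f"t{i}" for i in range(100)], n_samples=40, prevalence=0.4, seed=8
        )
        kept, dropped = filter_occurrences(occ, min_samples=15)
        brute_kept = [
            str(t) for t in occ.index if sum(int(x) for x in occ.loc[t]) > 15
        ]
        assert kept == brute_kept
        assert sorted(kept + dropped) == sorted(str(t) for t in occ.index)

    def test_permutation_invariance(self):
        occ = self.exact_count_matrix()
        rng = np.random.default_rng(0)
        shuffled = occ.iloc[rng.permutation(len(occ)), rng.permutation(occ.shape[1])]
        kept_a, _ = filter_occurrences(occ)
        kept_b, _ = filter_occurrences(shuffled)
        assert set(kept_a) == set(kept_b)

    def test_nonstrict_semantics_option(self):
        occ = self.exact_count_matrix()
        kept, _ = filter_occurrences(occ, min_samples=15, strict=False)
        assert "taxon_15" in kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_occurrences(self.exact_count_matrix(), min_samples=-1)

    def test_nonbinary_entries_rejected(self):
        occ = self.exact_count_matrix().astype(float)
        occ.iloc[0, 0] = 2.0
        with pytest.raises(ValueError, match="0/1"):
            filter_occurrences(occ)
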