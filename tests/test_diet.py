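import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodiet import diet
from phylodiet.diet import (
    CATEGORIES,
    DietEntry,
    dietary_indices,
    logit_with_boundary,
    normalize_entry,
    species_profile,
)
from phylodiet.errors import (
    DegenerateEntryError,
    UndefinedIndexError,
    ValidationError,
)


def entry(method="gut_percentage", species="Anas_test", **cats):
    return DietEntry(species=species, method=method, categories=cats)


class TestNormalizeEntry:
    def test_frequency_occurrence_rescaled_by_total(self):
        e = entry("frequency_occurrence", Leaves=60, Seeds=90, Animal=50)
        out = normalize_entry(e)
        assert out["Leaves"] == pytest.approx(30)
        assert out["Seeds"] == pytest.approx(45)
        assert out["Animal"] == pytest.approx(25)

    def test_gut_percentage_already_100_passes_through(self):
        e = entry(Leaves=55, Animal=40, Other=5)
        out = normalize_entry(e)
        assert out["Leaves"] == pytest.approx(55)
        assert out["Animal"] == pytest.approx(40)
        assert out["Other"] == pytest.approx(5)

    def test_qualitative_descriptors_scored_1_to_4(self):
        e = DietEntry(
            species="s",
            method="qualitative",
            categories={"Leaves": 1, "Seeds": 1},
            descriptors={"Leaves": "primarily", "Seeds": "rarely"},
        )
        out = normalize_entry(e)
        assert out["Leaves"] == pytest.approx(80)  # 4 / (4+1)
        assert out["Seeds"] == pytest.approx(20)

    def test_qualitative_without_descriptors_scores_items_equally(self):
        e = DietEntry(
            species="s",
            method="qualitative",
            categories={"Leaves": 1, "Seeds": 1, "Animal": 1},
        )
        out = normalize_entry(e)
        for c in ("Leaves", "Seeds", "Animal"):
            assert out[c] == pytest.approx(100 / 3)

    def test_custom_score_table(self):
        e = DietEntry(
            species="s",
            method="qualitative",
            categories={"Leaves": 1, "Seeds": 1},
            descriptors={"Leaves": "staple", "Seeds": "scant"},
        )
        out = normalize_entry(e, score_table={"staple": 3, "scant": 1})
        assert out["Leaves"] == pytest.approx(75)

    def test_off_100_percentage_entry_warns_and_renormalizes(self):
        e = entry(Leaves=80, Animal=40)  # sums to 120
        with pytest.warns(UserWarning):
            out = normalize_entry(e)
        assert sum(out.values()) == pytest.approx(100)

    def test_all_zero_entry_is_degenerate(self):
        with pytest.raises(DegenerateEntryError):
            DietEntry(species="s", method="gut_percentage",
                      categories={c: 0 for c in CATEGORIES})

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            entry(Leaves=-1, Animal=101)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            DietEntry(species="s", method="gut_percentage", categories={"Lichen": 100})

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            DietEntry(species="s", method="isotope", categories={"Leaves": 100})

    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=8, max_size=8,
        ).filter(lambda v: sum(v) > 1e-6)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalized_entries_sum_to_100(self, vals):
        e = entry("frequency_occurrence", **dict(zip(CATEGORIES, vals)))
        out = normalize_entry(e)
        assert sum(out.values()) == pytest.approx(100, abs=1e-9)


class TestSpeciesProfile:
    def test_single_entry_identity(self):
        p = species_profile([entry(Leaves=50, Animal=50)])
        assert p.mean_categories["Leaves"] == pytest.approx(50)
        assert p.n_entries == 1

    def test_equal_weight_across_entries(self):
        p = species_profile([entry(Leaves=100), entry(Animal=100)])
        assert p.mean_categories["Leaves"] == pytest.approx(50)
        assert p.mean_categories["Animal"] == pytest.approx(50)

    def test_mean_of_three(self):
        es = [entry(Leaves=v, Animal=100 - v) for v in (30, 60, 90)]
        p = species_profile(es)
        assert p.mean_categories["Leaves"] == pytest.approx(60)

    def test_entry_order_irrelevant(self):
        es = [entry(Leaves=v, Animal=100 - v) for v in (10, 40, 90)]
        p1 = species_profile(es)
        p2 = species_profile(es[::-1])
        assert p1.mean_categories == p2.mean_categories

    def test_sample_size_not_used_as_weight(self):
        e1 = entry(Leaves=100)
        e1.n_sampled = 1000
        e2 = entry(Animal=100)
        e2.n_sampled = 1
        p = species_profile([e1, e2])
        assert p.mean_categories["Leaves"] == pytest.approx(50)

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            species_profile([])

    def test_mixed_species_error(self):
        with pytest.raises(ValidationError):
            species_profile([entry(Leaves=100), entry(species="Other_sp", Animal=100)])


class TestDietaryIndices:
    def test_direct_arithmetic(self):
        h, f = dietary_indices(
            {"Leaves": 40, "Roots": 10, "Seeds": 30, "Animal": 10, "Other": 10}
        )
        assert h == pytest.approx(50 / 90)
        assert f == pytest.approx(40 / 90)

    def test_pure_animal_diet_is_zero(self):
        h, f = dietary_indices({"Animal": 100})
        assert h == 0 and f == 0

    def test_other_only_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            dietary_indices({"Other": 100})

    def test_scale_invariance(self):
        base = {"Leaves": 4, "Seeds": 3, "Animal": 2, "Other": 1}
        h1, f1 = dietary_indices(base)
        h2, f2 = dietary_indices({k: 7.3 * v for k, v in base.items()})
        assert h1 == pytest.approx(h2)
        assert f1 == pytest.approx(f2)

    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=8, max_size=8,
        ).filter(lambda v: sum(v[:7]) > 1e-6)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_folivory_never_exceeds_herbivory(self, vals):
        h, f = dietary_indices(dict(zip(CATEGORIES, vals)))
        assert 0 <= f <= h <= 1

    def test_round_trip_recovery_without_noise(self):
        # entries built exactly from a known category vector recover H
        cats = {"Leaves": 35, "Roots": 5, "Seeds": 20, "Plants": 10,
                "Algae": 5, "Animal": 20, "Other": 5}
        true_h = (35 + 5 + 10 + 5) / 95
        p = species_profile([entry(**cats), entry(**cats)])
        assert p.herbivory_index == pytest.approx(true_h, abs=1e-12)


class TestLogitWithBoundary:
    def test_midpoint_maps_to_zero(self):
        tv = logit_with_boundary({"s1": 0.5})
        assert tv.values["s1"] == pytest.approx(0.0)

    def test_zero_replaced_by_minimum_nonzero(self):
        tv = logit_with_boundary({"s1": 0.0, "s2": 0.2, "s3": 0.8})
        assert tv.values["s1"] == pytest.approx(math.log(0.25))
        assert tv.values["s2"] == pytest.approx(math.log(0.25))
        assert tv.values["s3"] == pytest.approx(-math.log(0.25))
        assert tv.transform_record == {"s1": 0.2}

    def test_one_replaced_by_maximum_nonone(self):
        tv = logit_with_boundary({"s1": 1.0, "s2": 0.9, "s3": 0.5})
        assert tv.values["s1"] == pytest.approx(tv.values["s2"])
        assert tv.transform_record == {"s1": 0.9}

    def test_monotonicity_preserved(self):
        tv = logit_with_boundary({"a": 0.1, "b": 0.4, "c": 0.7})
        assert tv.values["a"] < tv.values["b"] < tv.values["c"]

    def test_all_zero_has_no_replacement_candidate(self):
        with pytest.raises(ValidationError):
            logit_with_boundary({"a": 0.0, "b": 0.0})

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            logit_with_boundary({"a": 1.2})


class TestTables:
    def test_entry_frame_round_trip(self):
        es = [
            entry(Leaves=55, Animal=40, Other=5),
            DietEntry(
                species="Anas_test", method="qualitative",
                categories={"Leaves": 1}, descriptors={"Leaves": "primarily"},
            ),
        ]
        df = diet.entries_to_frame(es)
        back = diet.read_entries(df)
        assert len(back) == 2
        assert back[0].categories["Leaves"] == pytest.approx(55)
        assert back[1].descriptors["Leaves"] == "primarily"

    def test_compile_species_table(self):
        es = [entry(Leaves=100), entry(Animal=100), entry(species="B_sp", Seeds=100)]
        tab = diet.compile_species_table(es, masses={"Anas_test": 1000.0})
        tab = tab.set_index("species")
        assert tab.loc["Anas_test", "n_entries"] == 2
        assert tab.loc["Anas_test", "herbivory_index"] == pytest.approx(0.5)
        assert tab.loc["B_sp", "herbivory_index"] == pytest.approx(0.0)
        assert tab.loc["Anas_test", "body_mass_g"] == pytest.approx(1000.0)
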