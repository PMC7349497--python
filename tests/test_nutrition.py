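import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealscan import (
    COMPONENTS,
    FoodRecord,
    consumed,
    load_density_db,
    meal_report,
    volume_to_weight,
    weight_to_nutrients,
)
from mealscan.nutrition import DensityTableError

HEADER = (
    "food_id,density_g_per_cm3,kcal_per_g,carb_g_per_g,"
    "protein_g_per_g,sugar_g_per_g,fat_g_per_g"
)


def _db(tmp_path, rows, name="db.csv"):
    p = tmp_path / name
    p.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return p


@pytest.fixture
def mashed(tmp_path):
    p = _db(tmp_path, ["mashed_potatoes,1.03,1.13,0.17,0.02,0.014,0.042"])
    return load_density_db(p)["mashed_potatoes"]


class TestLoadDensityDb:
    def test_single_row(self, mashed):
        assert mashed.density == 1.03
        assert mashed.nutrients_per_g["carb_g"] == 0.17

    def test_duplicate_id_rejected(self, tmp_path):
        p = _db(tmp_path, ["a,1,1,0.1,0.1,0.1,0.1", "a,2,1,0.1,0.1,0.1,0.1"])
        with pytest.raises(DensityTableError, match="duplicate"):
            load_density_db(p)

    def test_negative_density_rejected_with_row(self, tmp_path):
        p = _db(tmp_path, ["a,1,1,0.1,0.1,0.1,0.1", "b,-0.5,1,0.1,0.1,0.1,0.1"])
        with pytest.raises(DensityTableError, match="row 3"):
            load_density_db(p)

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + ",color\n" + "a,1,1,0.1,0.1,0.1,0.1,red\n")
        with pytest.raises(DensityTableError, match="color"):
            load_density_db(p)

    def test_mass_fraction_over_one_rejected(self, tmp_path):
        p = _db(tmp_path, ["a,1,1,1.2,0.1,0.1,0.1"])
        with pytest.raises(DensityTableError, match="mass fraction"):
            load_density_db(p)

    def test_packaged_fixture_loads(self):
        from importlib import resources

        path = resources.files("mealscan.data").joinpath("densities.csv")
        db = load_density_db(path)
        assert len(db) == 6
        assert all(rec.density > 0 for rec in db.values())


class TestConversions:
    @pytest.mark.parametrize(
        "v,d,expect", [(100.0, 1.03, 103.0), (0.0, 2.0, 0.0), (343.0, 0.5, 171.5)]
    )
    def test_volume_to_weight(self, v, d, expect):
        assert volume_to_weight(v, d) == pytest.approx(expect, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            volume_to_weight(-1.0, 1.0)
        with pytest.raises(ValueError):
            volume_to_weight(1.0, 0.0)

    def test_weight_to_nutrients(self, mashed):
        cn = weight_to_nutrients(100.0, mashed)
        assert cn["carb_g"] == pytest.approx(17.0)
        assert weight_to_nutrients(0.0, mashed) == {c: 0.0 for c in COMPONENTS}

    def test_per_100g_table_path_equivalent(self):
        """Per-100 g source values divided by 100 match a native
        per-gram record."""
        per_100g = {"kcal": 113.0, "carb_g": 17.0, "protein_g": 2.0,
                    "sugar_g": 1.4, "fat_g": 4.2}
        rec = FoodRecord(
            "x", 1.0, {k: v / 100.0 for k, v in per_100g.items()}
        )
        cn = weight_to_nutrients(250.0, rec)
        for k, v in per_100g.items():
            assert cn[k] == pytest.approx(250.0 * v / 100.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        v=st.floats(0, 1e4),
        d=st.floats(0.01, 5),
        nd=st.floats(0, 1),
    )
    def test_linearity_and_mass_bound(self, v, d, nd):
        """Doubling V doubles W and CN; a mass fraction never yields
        more nutrient than weight."""
        rec = FoodRecord("x", d, {"carb_g": nd})
        w1 = volume_to_weight(v, d)
        w2 = volume_to_weight(2 * v, d)
        assert w2 == pytest.approx(2 * w1, rel=1e-12)
        cn = weight_to_nutrients(w1, rec)
        assert cn["carb_g"] <= w1 * (1 + 1e-12)


class TestConsumed:
    def test_basic_subtraction(self):
        acc = consumed({"carb_g": 50.0}, {"carb_g": 20.0})
        assert acc.consumed["carb_g"] == 30.0
        assert acc.warnings == []

    def test_leftover_equals_served(self):
        acc = consumed({"carb_g": 42.0}, {"carb_g": 42.0})
        assert acc.consumed["carb_g"] == 0.0
        assert acc.warnings == []

    def test_leftover_exceeds_served_flagged(self):
        acc = consumed({"carb_g": 10.0}, {"carb_g": 12.0})
        assert acc.consumed["carb_g"] == -2.0
        assert len(acc.warnings) == 1

    def test_component_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            consumed({"carb_g": 1.0}, {"fat_g": 1.0})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rn=st.floats(0, 1000),
        cn=st.floats(0, 1000),
    )
    def test_conservation(self, rn, cn):
        """CoN + CN = RN per component (to double-precision rounding of
        the single subtraction)."""
        acc = consumed({"carb_g": rn}, {"carb_g": cn})
        assert acc.consumed["carb_g"] + acc.leftover["carb_g"] == pytest.approx(
            rn, rel=1e-12, abs=1e-12
        )


class TestMealReport:
    def test_single_item_chain(self, mashed):
        db = {"mashed_potatoes": FoodRecord("mashed_potatoes", 1.0, {"carb_g": 0.15})}
        acc = meal_report([(100.0, "mashed_potatoes")], db, {"carb_g": 40.0})
        assert acc.consumed["carb_g"] == pytest.approx(25.0)

    def test_zero_items_whole_meal_consumed(self):
        acc = meal_report([], {}, {"carb_g": 40.0, "kcal": 300.0})
        assert acc.consumed == {"carb_g": 40.0, "kcal": 300.0}

    def test_two_items_summed_before_subtraction(self):
        db = {
            "a": FoodRecord("a", 1.0, {"carb_g": 0.1}),
            "b": FoodRecord("b", 2.0, {"carb_g": 0.1}),
        }
        acc = meal_report([(100.0, "a"), (100.0, "b")], db, {"carb_g": 50.0})
        assert acc.leftover["carb_g"] == pytest.approx(30.0)
        assert acc.consumed["carb_g"] == pytest.approx(20.0)

    def test_unknown_food_id(self):
        with pytest.raises(KeyError, match="mystery"):
            meal_report([(1.0, "mystery")], {}, {"carb_g": 1.0})
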