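"""Diet-quality index scorers: worked examples, ranges, invariances."""

import numpy as np
import pandas as pd
import pytest

import dietsurv as ds
from dietsurv import CohortStatisticError, DataError
from dietsurv.indexes import load_ahei2010_standards, load_hei2015_standards

from conftest import (
    AHEI_OPTIMAL_MAN,
    AHEI_WORST_MAN,
    BASE_DIET,
    HEI_OPTIMAL,
    HEI_WORST,
    diet_frame,
)


class TestDensity:
    def test_hand_arithmetic(self):
        assert ds.density(1.6, 2000.0) == pytest.approx(0.8)

    def test_zero_intake(self):
        assert ds.density(0.0, 1234.0) == 0.0

    def test_unit_energy_basis(self):
        assert ds.density(2.3, 1000.0) == pytest.approx(2.3)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(DataError):
            ds.density(1.0, 0.0)


class TestHei2015:
    def test_standards_file_contract(self):
        std = load_hei2015_standards()
        assert len(std) == 13
        assert std["max_points"].sum() == 100

    def test_optimal_diet_scores_100(self):
        res = ds.score_hei2015(diet_frame(HEI_OPTIMAL))
        assert res.total.iloc[0] == pytest.approx(100.0)

    def test_worst_diet_scores_0(self):
        res = ds.score_hei2015(diet_frame(HEI_WORST))
        assert res.total.iloc[0] == pytest.approx(0.0)

    def test_halfway_density_gives_half_points(self):
        # fruit density exactly halfway between min (0) and max (0.8)
        halfway = dict(HEI_OPTIMAL, fg_total_fruits=0.8, energy=2000.0)
        res = ds.score_hei2015(diet_frame(halfway))
        assert res.components["total_fruits"].iloc[0] == pytest.approx(2.5)

    def test_missing_component_column_names_it(self):
        df = diet_frame(BASE_DIET).drop(columns=["fg_dairy"])
        with pytest.raises(DataError, match="dairy"):
            ds.score_hei2015(df)

    def test_density_invariance(self):
        """Scaling all absolute intakes and energy together leaves the
        total unchanged (pure density/ratio scoring)."""
        row = dict(BASE_DIET)
        scaled = dict(row, energy=row["energy"] * 1.7,
                      **{k: v * 1.7 for k, v in row.items()
                         if k.startswith("fg_")},
                      nut_sodium_mg=row["nut_sodium_mg"] * 1.7,
                      nut_added_sugars_tsp=row["nut_added_sugars_tsp"] * 1.7)
        t0 = ds.score_hei2015(diet_frame(row)).total.iloc[0]
        t1 = ds.score_hei2015(diet_frame(scaled)).total.iloc[0]
        assert t1 == pytest.approx(t0)

    @pytest.mark.parametrize("component,column,low,high", [
        ("total_fruits", "fg_total_fruits", 0.2, 3.0),
        ("refined_grains", "fg_refined_grains", 1.0, 9.0),
    ])
    def test_monotone_in_component_intake(self, component, column, low, high):
        """Adequacy scores never decrease, moderation never increase,
        as the component's intake grows."""
        rows = [dict(BASE_DIET, **{column: x}) for x in np.linspace(low, high, 7)]
        pts = ds.score_hei2015(diet_frame(*rows)).components[component]
        deltas = np.diff(pts)
        direction = 1 if component == "total_fruits" else -1
        assert (direction * deltas >= -1e-12).all()

    def test_zero_sfa_gives_full_fatty_acid_points(self):
        row = dict(BASE_DIET, nut_sfa_pct=0.0, nut_mufa_pct=10.0, nut_pufa_pct=5.0)
        res = ds.score_hei2015(diet_frame(row))
        assert res.components["fatty_acids"].iloc[0] == pytest.approx(10.0)


class TestAhei2010:
    def test_standards_file_contract(self):
        assert len(load_ahei2010_standards()) == 10  # trans fat excluded

    def test_full_cutoffs_score_100(self):
        res = ds.score_ahei2010(diet_frame(AHEI_OPTIMAL_MAN))
        assert res.total.iloc[0] == pytest.approx(100.0)

    def test_zero_cutoffs_score_0(self):
        res = ds.score_ahei2010(diet_frame(AHEI_WORST_MAN))
        assert res.total.iloc[0] == pytest.approx(0.0)

    def test_midway_component_scores_5(self):
        # vegetables midway between 0 and 5 servings -> 2.5 servings
        row = dict(BASE_DIET, fg_veg_except_potatoes=1.25)  # *2 = 2.5 servings
        res = ds.score_ahei2010(diet_frame(row))
        assert res.components["vegetables"].iloc[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("drinks,gender,expected", [
        (1.0, "man", 10.0),    # inside men's window
        (1.0, "woman", 10.0),  # inside women's window
        (0.0, "man", 2.5),     # abstainer
        (3.5, "man", 0.0),     # at men's heavy cutoff
        (2.5, "woman", 0.0),   # at women's heavy cutoff
        (2.0, "woman", 5.0),   # midway between window top 1.5 and cutoff 2.5
    ])
    def test_alcohol_window(self, drinks, gender, expected):
        row = dict(BASE_DIET, gender=gender, nut_alcohol_drinks=drinks)
        res = ds.score_ahei2010(diet_frame(row))
        assert res.components["alcohol"].iloc[0] == pytest.approx(expected)

    def test_whole_grain_cutoff_is_gender_specific(self):
        # 80 g/day: full points for women (75 g cutoff), partial for men (90 g)
        grains = 80.0 / 28.35
        man = ds.score_ahei2010(
            diet_frame(dict(BASE_DIET, gender="man", fg_whole_grains=grains)))
        woman = ds.score_ahei2010(
            diet_frame(dict(BASE_DIET, gender="woman", fg_whole_grains=grains)))
        assert woman.components["whole_grains"].iloc[0] == pytest.approx(10.0)
        assert man.components["whole_grains"].iloc[0] == pytest.approx(80 / 90 * 10)


class TestAmed:
    def _cohort(self, special_row):
        rng = np.random.default_rng(12)
        rows = []
        for _ in range(20):
            rows.append({
                "fg_total_fruits": rng.uniform(0.5, 1.5),
                "fg_veg_except_potatoes": rng.uniform(0.8, 2.0),
                "fg_whole_grains": rng.uniform(0.3, 1.2),
                "fg_legumes": rng.uniform(0.05, 0.3),
                "fg_nuts_seeds": rng.uniform(0.1, 0.8),
                "fg_seafood": rng.uniform(0.2, 1.2),
                "fg_red_processed_meat": rng.uniform(1.0, 4.0),
                "nut_mufa_pct": rng.uniform(9, 14),
                "nut_sfa_pct": rng.uniform(8, 13),
                "nut_alcohol_g": rng.uniform(0, 40),
                "gender": "woman",
            })
        rows.append(special_row)
        return diet_frame(*rows)

    def test_perfect_adherent_man_scores_9(self):
        best = {
            "gender": "man",
            "fg_total_fruits": 5.0, "fg_veg_except_potatoes": 5.0,
            "fg_whole_grains": 5.0, "fg_legumes": 2.0, "fg_nuts_seeds": 3.0,
            "fg_seafood": 3.0, "fg_red_processed_meat": 0.0,
            "nut_mufa_pct": 20.0, "nut_sfa_pct": 5.0, "nut_alcohol_g": 15.0,
        }
        res = ds.score_amed(self._cohort(best))
        assert res.total.iloc[-1] == 9

    def test_man_alcohol_15g_gets_point(self):
        res = ds.score_amed(self._cohort(
            {"gender": "man", "nut_alcohol_g": 15.0}))
        assert res.components["alcohol"].iloc[-1] == 1

    def test_woman_alcohol_20g_gets_no_point(self):
        res = ds.score_amed(self._cohort(
            {"gender": "woman", "nut_alcohol_g": 20.0}))
        assert res.components["alcohol"].iloc[-1] == 0

    def test_all_criteria_failed_scores_0(self):
        worst = {
            "gender": "man",
            "fg_total_fruits": 0.0, "fg_veg_except_potatoes": 0.0,
            "fg_whole_grains": 0.0, "fg_legumes": 0.0, "fg_nuts_seeds": 0.0,
            "fg_seafood": 0.0, "fg_red_processed_meat": 99.0,
            "nut_mufa_pct": 1.0, "nut_sfa_pct": 20.0, "nut_alcohol_g": 0.0,
        }
        res = ds.score_amed(self._cohort(worst))
        assert res.total.iloc[-1] == 0

    def test_single_participant_cohort_rejected(self):
        with pytest.raises(CohortStatisticError):
            ds.score_amed(diet_frame(BASE_DIET))

    def test_permutation_invariance(self):
        df = self._cohort({"gender": "man", "nut_alcohol_g": 15.0})
        shuffled = df.sample(frac=1, random_state=5)
        a = ds.score_amed(df).total
        b = ds.score_amed(shuffled).total.sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_cutpoints_reported(self):
        res = ds.score_amed(self._cohort({"gender": "man"}))
        assert "fruits" in res.cutpoints
        assert res.cutpoints["alcohol"]["men"] == (10.0, 25.0)


class TestDash:
    def _cohort(self, n=25, seed=13):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            rows.append({
                "fg_total_fruits": rng.uniform(0.2, 2.5),
                "fg_veg_except_potatoes": rng.uniform(0.5, 2.5),
                "fg_whole_grains": rng.uniform(0.1, 2.0),
                "fg_nuts_seeds": rng.uniform(0.05, 1.0),
                "fg_legumes": rng.uniform(0.0, 0.4),
                "fg_lowfat_dairy": rng.uniform(0.0, 1.5),
                "fg_red_processed_meat": rng.uniform(0.5, 5.0),
                "nut_ssb_g": rng.uniform(0, 600),
                "nut_sodium_mg": rng.uniform(1500, 5000),
            })
        return diet_frame(*rows)

    def test_highest_fruit_quintile_gets_5(self):
        df = self._cohort()
        res = ds.score_dash(df)
        top = df["fg_total_fruits"].idxmax()
        assert res.components.loc[top, "fruits"] == 5

    def test_highest_sodium_quintile_gets_1(self):
        df = self._cohort()
        res = ds.score_dash(df)
        top = df["nut_sodium_mg"].idxmax()
        assert res.components.loc[top, "sodium"] == 1

    def test_extremal_totals_8_and_40(self):
        df = self._cohort()
        worst = {
            "fg_total_fruits": 0.0, "fg_veg_except_potatoes": 0.0,
            "fg_whole_grains": 0.0, "fg_nuts_seeds": 0.0, "fg_legumes": 0.0,
            "fg_lowfat_dairy": 0.0, "fg_red_processed_meat": 99.0,
            "nut_ssb_g": 9999.0, "nut_sodium_mg": 99999.0,
        }
        best = {
            "fg_total_fruits": 99.0, "fg_veg_except_potatoes": 99.0,
            "fg_whole_grains": 99.0, "fg_nuts_seeds": 99.0, "fg_legumes": 99.0,
            "fg_lowfat_dairy": 99.0, "fg_red_processed_meat": 0.0,
            "nut_ssb_g": 0.0, "nut_sodium_mg": 0.0,
        }
        # make every pre-existing value strictly interior
        df2 = pd.concat([df, diet_frame(worst, best)], ignore_index=True)
        res = ds.score_dash(df2)
        assert res.total.iloc[-2] == 8    # 5 adequacy x1 + 3 moderation x1
        assert res.total.iloc[-1] == 40   # 5x5 + 3x5

    def test_small_cohort_rejected(self):
        with pytest.raises(CohortStatisticError):
            ds.score_dash(self._cohort(n=4))

    def test_permutation_invariance(self):
        df = self._cohort()
        shuffled = df.sample(frac=1, random_state=3)
        a = ds.score_dash(df).total
        b = ds.score_dash(shuffled).total.sort_index()
        pd.testing.assert_series_equal(a, b)


class TestRangeConservation:
    def test_all_indexes_in_documented_ranges(self, cohort_5000):
        """On a generated cohort every total stays inside its range."""
        hei = ds.score_hei2015(cohort_5000).total
        ahei = ds.score_ahei2010(cohort_5000).total
        amed = ds.score_amed(cohort_5000).total
        dash = ds.score_dash(cohort_5000).total
        assert hei.between(0, 100).all()
        assert ahei.between(0, 100).all()
        assert amed.isin(range(10)).all()
        assert dash.between(8, 40).all()
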