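"""Shared fixtures: generated cohorts and hand-constructed diets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dietsurv as ds

#: A neutral, mid-range diet row carrying every column the index
#: crosswalk can reference. Tests override individual entries.
BASE_DIET = {
    "gender": "man",
    "energy": 2000.0,
    "fg_total_fruits": 1.0,
    "fg_whole_fruits": 0.7,
    "fg_fruit_juice": 0.3,
    "fg_total_vegetables": 1.8,
    "fg_veg_except_potatoes": 1.4,
    "fg_potatoes": 0.4,
    "fg_greens_beans": 0.2,
    "fg_dark_green_veg": 0.1,
    "fg_legumes": 0.1,
    "fg_whole_grains": 0.8,
    "fg_refined_grains": 5.0,
    "fg_dairy": 1.2,
    "fg_lowfat_dairy": 0.5,
    "fg_total_protein": 6.0,
    "fg_seafood": 0.7,
    "fg_red_processed_meat": 2.5,
    "fg_nuts_seeds": 0.4,
    "nut_sodium_mg": 3000.0,
    "nut_added_sugars_tsp": 14.0,
    "nut_sfa_pct": 10.5,
    "nut_mufa_pct": 12.0,
    "nut_pufa_pct": 7.0,
    "nut_epa_dha_mg": 80.0,
    "nut_ssb_g": 200.0,
    "nut_alcohol_g": 5.0,
    "nut_alcohol_drinks": 5.0 / 14.0,
}

#: Diet meeting every HEI-2015 optimum at 2000 kcal (all adequacy
#: densities at/above their maximum standards, moderation at best levels).
HEI_OPTIMAL = {
    **BASE_DIET,
    "fg_total_fruits": 2.0,
    "fg_whole_fruits": 1.0,
    "fg_total_vegetables": 2.2,
    "fg_legumes": 0.5,
    "fg_greens_beans": 0.5,
    "fg_whole_grains": 3.5,
    "fg_dairy": 3.0,
    "fg_total_protein": 6.0,
    "fg_seafood": 2.0,
    "fg_nuts_seeds": 1.0,
    "nut_mufa_pct": 12.0,
    "nut_pufa_pct": 8.0,
    "nut_sfa_pct": 7.0,
    "fg_refined_grains": 1.0,
    "nut_sodium_mg": 1000.0,
    "nut_added_sugars_tsp": 5.0,
}

#: Diet hitting the HEI-2015 floor: zero adequacy, worst moderation.
HEI_WORST = {
    **BASE_DIET,
    "fg_total_fruits": 0.0, "fg_whole_fruits": 0.0, "fg_total_vegetables": 0.0,
    "fg_legumes": 0.0, "fg_greens_beans": 0.0, "fg_whole_grains": 0.0,
    "fg_dairy": 0.0, "fg_total_protein": 0.0, "fg_seafood": 0.0,
    "fg_nuts_seeds": 0.0, "nut_mufa_pct": 0.0, "nut_pufa_pct": 0.0,
    "nut_sfa_pct": 16.0, "fg_refined_grains": 9.0, "nut_sodium_mg": 5000.0,
    "nut_added_sugars_tsp": 35.0,
}

#: Diet achieving every AHEI-2010 full-point cutoff for a man.
AHEI_OPTIMAL_MAN = {
    **BASE_DIET,
    "gender": "man",
    "fg_veg_except_potatoes": 2.5,   # 5 servings
    "fg_whole_fruits": 2.0,          # 4 servings
    "fg_whole_grains": 3.2,          # 90.7 g >= 90 g (men)
    "nut_ssb_g": 0.0,
    "fg_fruit_juice": 0.0,
    "fg_nuts_seeds": 1.0,
    "fg_red_processed_meat": 0.0,
    "nut_epa_dha_mg": 250.0,
    "nut_pufa_pct": 10.0,
    "nut_sodium_mg": 1000.0,
    "nut_alcohol_drinks": 1.0,       # inside 0.5-2.0 window
    "nut_alcohol_g": 14.0,
}

#: Diet at every AHEI-2010 zero-point cutoff for a man.
AHEI_WORST_MAN = {
    **BASE_DIET,
    "gender": "man",
    "fg_veg_except_potatoes": 0.0,
    "fg_whole_fruits": 0.0,
    "fg_whole_grains": 0.0,
    "nut_ssb_g": 500.0,
    "fg_fruit_juice": 0.0,
    "fg_nuts_seeds": 0.0,
    "fg_legumes": 0.0,
    "fg_red_processed_meat": 8.0,    # 2 servings
    "nut_epa_dha_mg": 0.0,
    "nut_pufa_pct": 1.5,
    "nut_sodium_mg": 4000.0,
    "nut_alcohol_drinks": 4.0,
    "nut_alcohol_g": 56.0,
}


def diet_frame(*rows: dict) -> pd.DataFrame:
    """Build a cohort table from diet-row dicts (missing keys filled
    from BASE_DIET)."""
    return pd.DataFrame([{**BASE_DIET, **row} for row in rows])


@pytest.fixture(scope="session")
def cohort_5000() -> pd.DataFrame:
    return ds.generate_cohort(ds.CohortConfig(n_participants=5000, seed=20))


@pytest.fixture(scope="session")
def survival_cohort() -> pd.DataFrame:
    """A scored cohort with TAC quintiles and simulated follow-up
    (null exposure effect) for survival-model tests."""
    df = ds.generate_cohort(ds.CohortConfig(n_participants=4000, seed=77))
    df = ds.add_tac(df)
    df["tac_energy_adjusted"] = ds.energy_adjust(df["tac_raw"], df["energy"])
    df["tac_group"] = ds.assign_quintiles(df["tac_energy_adjusted"]).groups
    sim = ds.SurvivalSimConfig(
        quintile_log_hr=(0.0, 0.0, 0.0, 0.0, 0.0),
        confounder_log_hr={"age": 0.04, "gender=woman": -0.3},
        seed=78,
    )
    return ds.simulate_survival(df, sim, quintile_col="tac_group")
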