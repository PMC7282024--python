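# Cohort table column dictionary

Columns written by `generate_cohort` and consumed by the scorers,
exclusion cascade and survival models. All intakes are per day.

## Identifiers, demographics, covariates

| column | type / values | units |
|---|---|---|
| `id` | integer | — |
| `age` | float, ≥ 30 | years |
| `gender` | `man`, `woman` | — |
| `race_ethnicity` | `white`, `black`, `hispanic`, `other` | — |
| `pir_band` | `<1.3`, `1.3-<1.85`, `>=1.85` | poverty-income ratio band |
| `marital` | `married`, `unmarried` | — |
| `physical_activity` | `sufficient`, `insufficient` | — |
| `smoking` | `never_former_ge3y`, `former_lt3y`, `current` | — |
| `bmi` | float | kg/m² |
| `history_cvd`, `history_diabetes`, `history_hypertension` | bool | — |
| `energy` | float, > 0 | kcal/day |
| `weight` | float, > 0, mean 1 | analysis/survey weight |
| `cluster` | integer | sampling-cluster label |

## Food groups (`fg_`)

Cup equivalents unless noted. Derived totals are exact sums of their
parts.

| column | units | note |
|---|---|---|
| `fg_whole_fruits`, `fg_fruit_juice` | cup eq | |
| `fg_total_fruits` | cup eq | = whole fruits + fruit juice |
| `fg_veg_except_potatoes`, `fg_potatoes` | cup eq | |
| `fg_total_vegetables` | cup eq | = veg except potatoes + potatoes |
| `fg_dark_green_veg`, `fg_legumes` | cup eq | |
| `fg_greens_beans` | cup eq | = dark green veg + legumes |
| `fg_whole_grains`, `fg_refined_grains` | oz eq | |
| `fg_dairy`, `fg_lowfat_dairy` | cup eq | |
| `fg_total_protein`, `fg_seafood`, `fg_red_processed_meat`, `fg_nuts_seeds` | oz eq | |

## Nutrients (`nut_`)

| column | units |
|---|---|
| `nut_sodium_mg` | mg |
| `nut_added_sugars_tsp` | teaspoon eq (1 tsp eq = 4.2 g = 16.8 kcal) |
| `nut_sfa_pct`, `nut_mufa_pct`, `nut_pufa_pct` | % of energy |
| `nut_epa_dha_mg` | mg |
| `nut_ssb_g` | g (237 g = 1 serving) |
| `nut_alcohol_g` | g |
| `nut_alcohol_drinks` | drinks (14 g = 1 drink) |

## Antioxidant compounds (`aox_`)

mg/day each: `aox_vitamin_c`, `aox_vitamin_e`, `aox_carotenoids`,
`aox_flavonoids`, `aox_isoflavones`, `aox_proanthocyanidins`.

## Flags, derived analysis columns

| column | meaning |
|---|---|
| `flag_ineligible_mortality` | mortality linkage ineligible |
| `flag_unreliable_recall` | unreliable/incomplete 24h recall |
| `flag_cancer_history` | cancer history |
| `flag_pregnant_bf` | pregnant or breastfeeding |
| `tac_raw` | Σ intake × VCE, mg VCE/day (`add_tac`) |
| `tac_energy_adjusted` | residual-method adjusted TAC (`energy_adjust`) |
| `score_hei2015`, `score_ahei2010`, `score_amed`, `score_dash` | index totals |
| `<exposure>_group` | quintile / score group label 1–5 |
| `person_years` | follow-up duration (≤ horizon) |
| `event` | death indicator |
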