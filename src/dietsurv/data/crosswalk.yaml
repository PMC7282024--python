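# Food-group crosswalk: maps each index's components onto cohort table columns.
#
# Each component entry:
#   columns: list of column names, or {column, scale} pairs; scaled values are summed
#   basis:   how the summed value enters scoring
#            density    - per 1000 kcal (needs energy column); optional post-sum `scale`
#            raw        - used as-is
#            pct_energy - value * kcal_per_unit / energy * 100
#            ratio      - sum(columns) / sum(denominator)
#
# The indexes group foods differently (e.g. aMED scores fish alone where HEI-2015
# pools seafood with plant proteins), hence one mapping per index. Serving-unit
# conversions are encoded as scales: 1 cup eq = 2 servings, 1 oz eq whole grains
# = 28.35 g, 237 g SSB = 1 serving, 0.5 cup legumes = 1 serving, 4 oz meat =
# 1 serving, 0.25 cup legumes = 1 oz eq protein.
hei2015:
  total_fruits: {columns: [fg_total_fruits], basis: density}
  whole_fruits: {columns: [fg_whole_fruits], basis: density}
  total_vegetables: {columns: [fg_total_vegetables, fg_legumes], basis: density}
  greens_and_beans: {columns: [fg_greens_beans], basis: density}
  whole_grains: {columns: [fg_whole_grains], basis: density}
  dairy: {columns: [fg_dairy], basis: density}
  total_protein_foods: {columns: [fg_total_protein], basis: density}
  seafood_plant_proteins:
    columns: [fg_seafood, fg_nuts_seeds, {column: fg_legumes, scale: 4.0}]
    basis: density
  fatty_acids:
    columns: [nut_mufa_pct, nut_pufa_pct]
    denominator: [nut_sfa_pct]
    basis: ratio
  refined_grains: {columns: [fg_refined_grains], basis: density}
  sodium: {columns: [nut_sodium_mg], basis: density, scale: 0.001}
  added_sugars: {columns: [nut_added_sugars_tsp], basis: pct_energy, kcal_per_unit: 16.8}
  saturated_fats: {columns: [nut_sfa_pct], basis: raw}

ahei2010:
  vegetables: {columns: [{column: fg_veg_except_potatoes, scale: 2.0}], basis: raw}
  fruit: {columns: [{column: fg_whole_fruits, scale: 2.0}], basis: raw}
  whole_grains: {columns: [{column: fg_whole_grains, scale: 28.35}], basis: raw}
  ssb_fruit_juice:
    columns: [{column: nut_ssb_g, scale: 0.004219}, fg_fruit_juice]
    basis: raw
  nuts_legumes:
    columns: [fg_nuts_seeds, {column: fg_legumes, scale: 2.0}]
    basis: raw
  red_processed_meat: {columns: [{column: fg_red_processed_meat, scale: 0.25}], basis: raw}
  epa_dha: {columns: [nut_epa_dha_mg], basis: raw}
  pufa: {columns: [nut_pufa_pct], basis: raw}
  sodium: {columns: [nut_sodium_mg], basis: raw}
  alcohol: {columns: [nut_alcohol_drinks], basis: raw}

amed:
  fruits: {columns: [fg_total_fruits], direction: above_median}
  vegetables: {columns: [fg_veg_except_potatoes], direction: above_median}
  whole_grains: {columns: [fg_whole_grains], direction: above_median}
  legumes: {columns: [fg_legumes], direction: above_median}
  nuts: {columns: [fg_nuts_seeds], direction: above_median}
  fish: {columns: [fg_seafood], direction: above_median}
  red_processed_meat: {columns: [fg_red_processed_meat], direction: below_median}
  mufa_sfa_ratio:
    columns: [nut_mufa_pct]
    denominator: [nut_sfa_pct]
    basis: ratio
    direction: above_median
  alcohol:
    columns: [nut_alcohol_g]
    direction: window
    window_men: [10.0, 25.0]
    window_women: [5.0, 15.0]

dash:
  fruits: {columns: [fg_total_fruits], direction: adequacy}
  vegetables: {columns: [fg_veg_except_potatoes], direction: adequacy}
  whole_grains: {columns: [fg_whole_grains], direction: adequacy}
  nuts_legumes:
    columns: [fg_nuts_seeds, {column: fg_legumes, scale: 2.0}]
    direction: adequacy
  lowfat_dairy: {columns: [fg_lowfat_dairy], direction: adequacy}
  red_processed_meat: {columns: [fg_red_processed_meat], direction: moderation}
  ssb: {columns: [nut_ssb_g], direction: moderation}
  sodium: {columns: [nut_sodium_mg], direction: moderation}
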