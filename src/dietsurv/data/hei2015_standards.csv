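# HEI-2015 component scoring standards (Krebs-Smith et al., J Acad Nutr Diet 2018).
# All components scored on a per-1000 kcal density basis except fatty_acids
# ((MUFA+PUFA)/SFA ratio) and the %-energy moderation components.
# adequacy: 0 points at/below min_standard, max_points at/above max_standard, linear between.
# moderation: max_points at/below max_standard (best level), 0 at/above min_standard (worst).
name,direction,max_points,min_standard,max_standard,unit
total_fruits,adequacy,5,0.0,0.8,cup eq per 1000 kcal
whole_fruits,adequacy,5,0.0,0.4,cup eq per 1000 kcal
total_vegetables,adequacy,5,0.0,1.1,cup eq per 1000 kcal
greens_and_beans,adequacy,5,0.0,0.2,cup eq per 1000 kcal
whole_grains,adequacy,10,0.0,1.5,oz eq per 1000 kcal
dairy,adequacy,10,0.0,1.3,cup eq per 1000 kcal
total_protein_foods,adequacy,5,0.0,2.5,oz eq per 1000 kcal
seafood_plant_proteins,adequacy,5,0.0,0.8,oz eq per 1000 kcal
fatty_acids,adequacy,10,1.2,2.5,(MUFA+PUFA)/SFA ratio
refined_grains,moderation,10,4.3,1.8,oz eq per 1000 kcal
sodium,moderation,10,2.0,1.1,g per 1000 kcal
added_sugars,moderation,10,26.0,6.5,% of energy
saturated_fats,moderation,10,16.0,8.0,% of energy
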