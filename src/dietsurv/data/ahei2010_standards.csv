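# AHEI-2010 component scoring cutoffs (Chiuve et al., J Nutr 2012), 10-component
# variant without trans fat. Each component is worth 10 points, scored linearly
# between zero_cutoff (0 points) and full_cutoff (10 points); for moderation
# components zero_cutoff > full_cutoff. Gender-specific cutoffs, where the source
# defines them, override the gender-neutral ones (whole grains, alcohol).
# Sodium was decile-based in the source cohort; the fixed mg/day cutoffs below are
# the source cohort's extreme-decile medians, used here as linear cutoffs.
# The alcohol row is a window component: full points inside [window_low, window_high]
# drinks/day, 0 points at/above the gender's zero_cutoff, abstainers receive
# abstainer_points.
name,direction,zero_cutoff,full_cutoff,full_cutoff_men,full_cutoff_women,zero_cutoff_men,zero_cutoff_women,window_low_men,window_high_men,window_low_women,window_high_women,abstainer_points,unit
vegetables,adequacy,0.0,5.0,,,,,,,,,,servings/day
fruit,adequacy,0.0,4.0,,,,,,,,,,servings/day
whole_grains,adequacy,0.0,,90.0,75.0,,,,,,,,g/day
ssb_fruit_juice,moderation,1.0,0.0,,,,,,,,,,servings/day
nuts_legumes,adequacy,0.0,1.0,,,,,,,,,,servings/day
red_processed_meat,moderation,1.5,0.0,,,,,,,,,,servings/day
epa_dha,adequacy,0.0,250.0,,,,,,,,,,mg/day
pufa,adequacy,2.0,10.0,,,,,,,,,,% of energy
sodium,moderation,3337.0,1112.0,,,,,,,,,,mg/day
alcohol,window,,,,,3.5,2.5,0.5,2.0,0.5,1.5,2.5,drinks/day
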