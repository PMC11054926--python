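# AHS-2 strict-vegetarian (vegan) nutrient densities per 2000 kcal/day.
# Fiber is stored as the cohort mean 46.7 g (displayed as 47 at integer
# precision); energy fractions for protein (14.5 %), saturated fat (5 %)
# and the plant-protein leucine share (7.1 %) ride in the metadata.
# name = ahs2_strict_vegetarian
# reference_energy = 2000
# protein_energy_fraction = 0.145
# saturated_fat_energy_fraction = 0.05
# leucine_fraction_of_protein = 0.071
nutrient_id,amount,unit,precision
saturated_fat,5,pct_kcal,0
omega3_pufa,2,g,1
linoleic_acid,19.5,g,0
fiber,46.7,g,0
vitamin_a,1108,mcg_RAE,0
vitamin_b6,14.4,mg,1
folate,888,mcg,0
vitamin_b12,23.3,mcg,1
vitamin_c,531,mg,0
vitamin_d,252,IU,0
vitamin_e,101,mg,0
calcium,1156,mg,0
iron,32,mg,0
magnesium,652,mg,0
phosphorus,1371,mg,0
potassium,4234,mg,0
sodium,3531,mg,0
zinc,16,mg,0
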