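nutrient_id,target,unit,basis,direction,strict,energy_relative_rule
saturated_fat,10,pct_kcal,DGA_limit,limit,true,
omega3_pufa,1.6,g,AI,minimum,false,
linoleic_acid,17,g,AI,minimum,false,
fiber,59,g,AI,minimum,false,14
vitamin_a,900,mcg_RAE,RDA,minimum,false,
vitamin_b6,1.3,mg,RDA,minimum,false,
folate,400,mcg,RDA,minimum,false,
vitamin_b12,2.4,mcg,RDA,minimum,false,
vitamin_c,90,mg,RDA,minimum,false,
vitamin_d,600,IU,RDA,minimum,false,
vitamin_e,15,mg,RDA,minimum,false,
calcium,1000,mg,RDA,minimum,false,
iron,8,mg,RDA,minimum,false,
magnesium,400,mg,RDA,minimum,false,
phosphorus,700,mg,RDA,minimum,false,
potassium,3400,mg,AI,minimum,false,
sodium,2300,mg,CDRR,limit,false,
zinc,11,mg,RDA,minimum,false,
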