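nutrient_id,unit,schema,sex,age_min,age_max,ear,sd,ul,target_max,supplement_counted,provenance
protein,%E,adequacy,,18,,10,,35,,True,placeholder: AMDR-style energy-fraction band for adult protein
carbohydrate,%E,adequacy,,18,,45,,65,,False,placeholder: AMDR-style energy-fraction band for carbohydrate
total_fat,%E,moderation,,18,,,,,35,True,placeholder: upper end of adult total-fat energy-fraction range
mufa,%E,adequacy,,18,,10,,25,,False,placeholder: monounsaturated-fat energy-fraction band
pufa,%E,adequacy,,18,,6,,11,,False,placeholder: polyunsaturated-fat energy-fraction band
sfa,%E,moderation,,18,,,,,10,True,placeholder: population target maximum for saturated fat
salt,g/day,moderation,,18,,,,,6,False,placeholder: population target maximum for salt
omega3,g/day,adequacy,,18,,1.1,,3.0,,True,placeholder: adult omega-3 (ALA-equivalent) adequate-intake level; graded in g/day
fiber,g/day,adequacy,,18,,25,,70,,False,placeholder: adult dietary fiber adequate-intake level; generous upper bound
calcium,mg/day,adequacy,,18,,800,80,2500,,True,placeholder: adult calcium EAR and UL
iron,mg/day,adequacy,F,18,,8.1,,45,,True,placeholder: adult female iron EAR (menstruating women) and UL
iron,mg/day,adequacy,M,18,,6.0,,45,,True,placeholder: adult male iron EAR and UL
vitamin_a,ug/day,adequacy,F,18,,500,,3000,,True,placeholder: adult female vitamin A EAR (retinol activity equivalents) and UL
vitamin_a,ug/day,adequacy,M,18,,625,,3000,,True,placeholder: adult male vitamin A EAR and UL
folate,ug/day,adequacy,,18,,320,,1000,,True,placeholder: adult folate EAR (dietary folate equivalents) and UL
thiamin,mg/day,adequacy,,18,,1.0,,50,,True,placeholder: adult thiamin EAR; upper bound is a cushion (no established UL)
riboflavin,mg/day,adequacy,,18,,1.1,,100,,True,placeholder: adult riboflavin EAR; upper bound is a cushion (no established UL)
vitamin_b12,ug/day,adequacy,,18,,2.0,,60,,True,placeholder: adult vitamin B12 EAR; upper bound is a cushion (no established UL)
vitamin_c,mg/day,adequacy,,18,,75,,2000,,True,placeholder: adult vitamin C EAR and UL
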