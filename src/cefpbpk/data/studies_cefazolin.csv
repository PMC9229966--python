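# Packaged cefazolin study designs (dose, infusion, population, demographics).
# population_class is the pre-pregnancy baseline used for tissue flows.
# weight_target_kg is the reported mean weight at study time (at GA for
# pregnant studies); blank = use the class default. Ages default to 20-40
# where the source study stated none.
study_code,population_class,pregnant,ga_weeks,dose_mg,infusion_min,n_subjects,prop_female,age_min,age_max,weight_target_kg,pre_pregnancy_weight_kg
001,lean,0,,500,2,6,1.0,20,40,62.3,
002,lean,0,,1000,2,17,0.0,21,42,,
003,lean,1,24.5,500,2,6,1.0,20,40,67.9,
004,lean,1,39.1,2000,4,10,1.0,23,32,65.7,
005,lean,1,39,1000,1,20,1.0,23,43,79.3,
006,obese,0,,2000,1,37,0.7,18,60,127,
007,obese,1,39.3,2000,3,13,1.0,23.5,34,113.6,
008,obese,1,39,3000,3,13,1.0,30,35,108,
009,obese,1,39.2,2000,1,28,1.0,25.5,34,103,
0091,morbidly_obese,1,38.75,2000,0.75,11,1.0,25,37,129.14,
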