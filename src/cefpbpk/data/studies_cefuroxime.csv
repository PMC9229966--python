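# Packaged cefuroxime study designs. Codes 1-4 are the prospective
# caesarean-prophylaxis scenarios (750/1500 mg in obese and morbidly obese
# pregnant populations, pre-pregnancy weights 80/105 kg).
study_code,population_class,pregnant,ga_weeks,dose_mg,infusion_min,n_subjects,prop_female,age_min,age_max,weight_target_kg,pre_pregnancy_weight_kg
01,lean,0,,1500,2,12,0.5,20,40,,
02,lean,0,,750,1,7,1.0,20,40,61.7,
03,lean,0,,1500,30,23,0.26,19,31,76,
04,lean,0,,750,20,10,0.5,18,48,72,
05,lean,0,,1500,20,10,0.5,18,48,72,
06,lean,1,29,750,1,7,1.0,20,40,64.4,
07,lean,1,40,750,1,7,1.0,20,40,74,
08,lean,1,39.5,1500,1,18,1.0,23,37,78.94,
09,lean,1,39,1500,1,10,1.0,20,32,74.4,
091,lean,1,39,1500,1,10,1.0,20,36,70.3,
092,morbidly_obese,0,,1500,15,6,1.0,19,76,131.66,
1,obese,1,39.5,750,1,50,1.0,23,37,97.8,80
2,obese,1,39.5,1500,1,50,1.0,23,37,97.8,80
3,morbidly_obese,1,39.5,750,1,50,1.0,23,37,128,105
4,morbidly_obese,1,39.5,1500,1,50,1.0,23,37,128,105
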