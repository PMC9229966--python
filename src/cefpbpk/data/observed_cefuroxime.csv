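# Printed observed clinical values for the cefuroxime studies.
study_code,drug,dose_mg,quantity,matrix,time_min,value,dispersion_type,dispersion_value,known_failure,note
01,cefuroxime,1500,conc,plasma_total,10,130.8,,,0,
01,cefuroxime,1500,conc,adipose_total,10,16.5,,,1,
02,cefuroxime,750,auc,,,60.8,,,0,
02,cefuroxime,750,conc,plasma_total,9.6,51.48,,,0,
02,cefuroxime,750,cl,,,11.9,,,0,
03,cefuroxime,1500,auc,,,124,,,0,
03,cefuroxime,1500,conc,plasma_total,16.8,56.35,,,0,
03,cefuroxime,1500,cl,,,12.09,,,0,
04,cefuroxime,750,auc,,,77,,,0,
04,cefuroxime,750,conc,plasma_total,20,75.29,,,0,
04,cefuroxime,750,cl,,,9.74,,,0,
05,cefuroxime,1500,auc,,,137,,,0,
05,cefuroxime,1500,conc,plasma_total,18,82.08,,,0,
05,cefuroxime,1500,cl,,,10.9,,,0,
06,cefuroxime,750,auc,,,42.0,,,0,
06,cefuroxime,750,conc,plasma_total,7.8,43.56,,,0,
06,cefuroxime,750,cl,,,16.9,,,0,
07,cefuroxime,750,auc,,,46.7,,,0,
07,cefuroxime,750,conc,plasma_total,9,43.83,,,0,
07,cefuroxime,750,cl,,,15.5,,,0,
09,cefuroxime,1500,conc,plasma_total,30,55.2,,,0,
091,cefuroxime,1500,conc,plasma_total,48,74.8,,,0,
092,cefuroxime,1500,auc,,,158.7,,,0,
092,cefuroxime,1500,conc,plasma_total,30,64.25,,,0,
092,cefuroxime,1500,cl,,,8.39,,,0,
092,cefuroxime,1500,conc,adipose_isf_unbound,,36.06,,,0,
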