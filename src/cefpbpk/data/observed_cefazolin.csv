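# Printed observed clinical values for the cefazolin studies.
# quantity: auc (mg/L*h), cl (L/h), conc (ug/mL or ug/g at time_min; time_min
# blank means the study reported Cmax). matrix applies to conc rows.
# known_failure=1 marks comparisons the source itself reports as outside the
# two-fold window. note flags printed inconsistencies carried verbatim.
study_code,drug,dose_mg,quantity,matrix,time_min,value,dispersion_type,dispersion_value,known_failure,note
001,cefazolin,500,auc,,,110,,,0,
001,cefazolin,500,conc,plasma_total,10.8,73.24,,,0,
001,cefazolin,500,cl,,,4.04,,,0,
002,cefazolin,1000,auc,,,236.15,,,0,printed as dose/cl but 1000/3.8 != 236.15
002,cefazolin,1000,conc,plasma_total,4.4,188.6,,,0,
002,cefazolin,1000,cl,,,3.8,,,0,
003,cefazolin,500,auc,,,75.7,,,0,
003,cefazolin,500,conc,plasma_total,9,60.07,,,0,
003,cefazolin,500,cl,,,7.3,,,0,
004,cefazolin,2000,conc,plasma_total,82,57.2,,,0,
004,cefazolin,2000,conc,adipose_total,31.5,8.7,iqr,5.7-11.2,0,
005,cefazolin,1000,auc,,,139.27,,,0,
005,cefazolin,1000,conc,plasma_total,,82.53,,,0,
005,cefazolin,1000,cl,,,7.18,,,0,
006,cefazolin,2000,conc,plasma_total,16,159.96,,,0,
006,cefazolin,2000,conc,adipose_total,16,8.78,,,0,
007,cefazolin,2000,auc,,,234.3,,,0,
007,cefazolin,2000,conc,plasma_total,,146.15,,,0,
007,cefazolin,2000,cl,,,8.4,,,0,
007,cefazolin,2000,conc,adipose_total,25,12.4,,,0,
008,cefazolin,3000,auc,,,453.4,,,0,
008,cefazolin,3000,conc,plasma_total,,223.74,,,0,
008,cefazolin,3000,cl,,,6.6,,,0,
008,cefazolin,3000,conc,adipose_total,28,16.8,,,0,
009,cefazolin,2000,conc,plasma_total,24.5,100.7,,,0,
009,cefazolin,2000,conc,adipose_total,24.5,9.4,,,0,
0091,cefazolin,2000,conc,plasma_total,12,155.45,,,0,
0091,cefazolin,2000,conc,adipose_total,12,18.36,sd,6.68,1,
0091,cefazolin,2000,conc,adipose_total,60,21.73,sd,16.02,1,
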