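# Printed predicted/observed pairs and their published ratio for cefuroxime.
study_code,quantity,observed,predicted,ratio_printed,known_failure
01,conc,130.8,91.04,0.70,0
02,auc,60.8,75.79,1.25,0
02,conc,51.48,52.19,1.01,0
02,cl,11.9,12.14,1.02,0
03,auc,124,153.89,1.24,0
03,conc,56.35,65.21,1.16,0
03,cl,12.09,10.99,0.91,0
04,auc,77,78.03,1.01,0
04,conc,75.29,58.61,0.78,0
04,cl,9.74,11.48,1.18,0
05,auc,137,157.20,1.15,0
05,conc,82.08,110.83,1.35,0
05,cl,10.9,11.48,1.05,0
06,auc,42.0,61.09,1.45,0
06,conc,43.56,45.29,1.04,0
06,cl,16.9,11.98,0.71,0
07,auc,46.7,63.33,1.36,0
07,conc,43.83,39.73,0.91,0
07,cl,15.5,11.57,0.75,0
09,conc,55.2,56.02,1.01,0
091,conc,74.8,45.51,0.61,0
092,auc,158.7,130.76,0.82,0
092,conc,64.25,48.13,0.75,0
092,cl,8.39,12.33,1.47,0
01,adipose_conc,16.5,6.55,0.40,1
092,adipose_isf_conc,36.06,33.74,0.94,0
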