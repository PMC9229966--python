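# Printed predicted/observed pairs and their published ratio for cefazolin
# (plasma AUC, concentration-at-time, clearance, and adipose concentration
# comparisons). known_failure=1 marks the published out-of-two-fold rows.
study_code,quantity,observed,predicted,ratio_printed,known_failure
001,auc,110,130.27,1.18,0
001,conc,73.24,66.26,0.90,0
001,cl,4.04,3.91,0.97,0
002,auc,236.15,262.60,1.11,0
002,conc,188.6,152.72,0.81,0
002,cl,3.8,4.01,1.06,0
003,auc,75.7,84.37,1.11,0
003,conc,60.07,57.38,0.96,0
003,cl,7.3,6.22,0.85,0
004,conc,57.2,95.74,1.67,0
005,auc,139.27,172.24,1.24,0
005,conc,82.53,105.60,1.28,0
005,cl,7.18,5.99,0.83,0
006,conc,159.96,131.55,0.82,0
007,auc,234.3,307.48,1.31,0
007,conc,146.15,163.31,1.12,0
007,cl,8.4,6.17,0.73,0
008,auc,453.4,446.82,0.99,0
008,conc,223.74,249.68,1.12,0
008,cl,6.6,6.35,0.96,0
009,conc,100.7,116.01,1.15,0
0091,conc,155.45,115.28,0.74,0
004,adipose_conc,8.7,14.21,1.63,0
006,adipose_conc,8.78,9.18,1.05,0
007,adipose_conc,12.4,9.85,0.79,0
008,adipose_conc,16.8,14.39,0.86,0
009,adipose_conc,9.4,10.08,1.07,0
0091,adipose_conc,18.36,8.89,0.48,1
0091,adipose_conc_late,21.73,6.85,0.32,1
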