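# Reference organ volumes and regional blood flows for the virtual subjects.
# vol_per_kg_lbw: organ volume (L) per kg of lean body weight (reference-adult
# derived; adipose and the residual carcass compartment are computed at run
# time from fat mass and mass closure respectively, hence blank here).
# flow_frac_*: fraction of cardiac output perfusing the tissue for each
# non-pregnant baseline class; each column sums to 1 (lungs are in series and
# receive the whole cardiac output). Obese classes shift flow toward adipose.
tissue,vol_per_kg_lbw,flow_frac_lean,flow_frac_obese,flow_frac_morbidly_obese
adipose,,0.050,0.090,0.110
bone,0.1872,0.050,0.045,0.045
brain,0.02585,0.120,0.100,0.095
gut,0.02941,0.150,0.140,0.135
heart,0.005882,0.040,0.040,0.040
kidney,0.005526,0.190,0.170,0.160
liver,0.03209,0.065,0.065,0.065
lung,0.008913,,,
muscle,0.5169,0.170,0.150,0.140
pancreas,0.002496,0.010,0.010,0.010
skin,0.06061,0.050,0.050,0.050
spleen,0.002674,0.030,0.030,0.030
rest,,0.075,0.110,0.120
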