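# Gestational scaling used on the non-pregnant baseline.
# kind=exp_sat: multiplier 1 + a*(1 - exp(-GA/b))      (GA in weeks)
# kind=power:   added mass (kg) a*(GA/40)**b
# Multipliers apply to the named baseline quantity; masses are the
# non-adipose components of gestational weight gain. Adipose gain is the
# residual against the target term weight (or the fat_default curve when no
# target is supplied).
parameter,kind,a,b
cardiac_output,exp_sat,0.45,12
gfr,exp_sat,0.50,8
plasma_volume,exp_sat,0.45,14
red_cell_volume,exp_sat,0.25,16
fetus,power,3.5,2.6
conceptus_other,power,2.8,1.5
ecf_expansion,power,1.5,2.0
fat_default,power,3.5,2.0
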