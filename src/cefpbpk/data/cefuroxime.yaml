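# Cefuroxime compound file. The measured shake-flask log P (-1.5) is used;
# the model is insensitive to the older predicted value (-0.9).
# Absent transporters are encoded as 0 (no OAT3 route for cefuroxime).
name: cefuroxime
molecular_weight: 424.39
log_p: -1.5
compound_type: monoprotic_acid
acid_pka: 3.15
blood_to_plasma: 0.56
fu_plasma: 0.67
kp_scalar: 1.0
adipose_clpd_l_per_h: 0.1
kp_overrides:
  lung: 0.43
  muscle: 0.25
  skin: 0.53
  kidney: 0.36
renal:
  clint_oat1_uptake: 9.62      # optimised total basolateral uptake
  clint_oat3_uptake: 0.0
  clint_mrp4_efflux: 10.0
  clpd_basal: 0.0
  clpd_apical: 0.0
  fu_kidney_cell: 1.0
  fu_urine: 1.0
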