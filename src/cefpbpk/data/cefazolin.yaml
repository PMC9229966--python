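# Cefazolin compound file: physicochemical and kinetic constants for the
# whole-body PBPK model. Concentration units mg/L (== ug/mL), clearances L/h
# unless a key name says otherwise.
name: cefazolin
molecular_weight: 454.5        # g/mol
log_p: -0.58                   # octanol:water, shake-flask literature value
compound_type: monoprotic_acid
acid_pka: 3.6
blood_to_plasma: 0.55
fu_plasma: 0.225
kp_scalar: 1.0
adipose_clpd_l_per_h: 0.1      # passive ISF<->IW diffusion clearance
kp_overrides:                  # tissue:plasma partition coefficients pinned
  lung: 0.2                    # mean rat/rabbit value
  muscle: 0.03
  skin: 0.09
  kidney: 0.21
renal:
  # per-cell intrinsic clearances, uL/min/1e6 proximal-tubule cells
  clint_oat1_uptake: 0.208
  clint_oat3_uptake: 7.28
  clint_mrp4_efflux: 41.43
  # passive diffusion across kidney-cell membranes, mL/min/1e6 cells
  clpd_basal: 2.07e-8
  clpd_apical: 2.07e-8
  fu_kidney_cell: 1.0
  fu_urine: 1.0
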