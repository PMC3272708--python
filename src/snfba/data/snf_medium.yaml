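# Symbiotic microaerobic / nutrient-sharing medium for bacteroid FBA.
# Bounds are (lower, upper) in mmol/gDW/hr; uptake is negative flux through
# an exchange reaction written "M[e] ->". The carbon_source selects which
# C4-dicarboxylate exchange stays open; the other is closed on application.
carbon_source: malate
malate_exchange: EX_mal_e
succinate_exchange: EX_succ_e
exchanges:
  EX_mal_e: [-1.112, 1000.0]     # plant-supplied malate
  EX_succ_e: [-1.326, 1000.0]    # plant-supplied succinate (alternative)
  EX_o2_e: [-1.26, 1000.0]       # microaerobic oxygen cap
  EX_inost_e: [-0.01, 1000.0]    # inositol sink, origin unknown
  EX_glu_e: [-1000.0, 1000.0]    # glutamate freely imported or effused
  EX_n2_e: [-1000.0, 1000.0]     # dinitrogen
  EX_fe2_e: [-1000.0, 1000.0]    # iron
  EX_so4_e: [-1000.0, 1000.0]    # sulfate
  EX_pi_e: [-1000.0, 1000.0]     # phosphate
  EX_hco_e: [-0.01, 1000.0]      # homocitrate (plant-supplied, trace)
  EX_mg2_e: [-1000.0, 1000.0]    # magnesium
  EX_mobd_e: [-1000.0, 1000.0]   # molybdate
  EX_h_e: [-1000.0, 1000.0]      # protons
  EX_co2_e: [-1000.0, 1000.0]    # carbon dioxide
  EX_h2o_e: [-1000.0, 1000.0]    # water
  EX_nh3_e: [0.0, 1000.0]        # ammonia export to the plant
  EX_ala_e: [0.0, 1000.0]        # alanine export to the plant
  EX_asp_e: [0.0, 1000.0]        # aspartate export to the plant
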