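{
  "elements": ["Al", "Be", "Ba", "Ca", "Cd", "Co", "Cr", "Cu", "Fe", "Mg", "Mn", "Mo", "Ni", "Pb", "V", "Zn"],
  "soil_median": {"Al": 196.0533, "Be": 0.4422, "Ba": 2.442, "Ca": 883.5467, "Cd": 0.106, "Co": 0.519, "Cr": 0.6619, "Cu": 3.0313, "Fe": 26.2683, "Mg": 65.303, "Mn": 2.8454, "Mo": 0.0383, "Ni": 0.2883, "Pb": 0.1553, "V": 0.2692, "Zn": 42.4307},
  "enrichment": {"Al": 5.1183, "Be": 28.29, "Ba": 3.3319, "Ca": 10.611, "Cd": 2.7169, "Co": 6.4979, "Cr": 2.5215, "Cu": 22.586, "Fe": 17.825, "Mg": 27.394, "Mn": 4.5726, "Mo": 15.919, "Ni": 5.9092, "Pb": 19.774, "V": 4.6089, "Zn": 2.0687},
  "site_effect": {"Site I": 1.0, "Site II": 1.0},
  "dispersion": 0.3,
  "n_replicates": 3,
  "seed": 0
}
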