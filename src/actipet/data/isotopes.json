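{
  "11C": {
    "name": "11C",
    "half_life_min": 20.364,
    "reaction_channel": "14N(p,X)11C",
    "threshold_MeV": 3.13,
    "integrated_xs_mb_MeV": 75.1,
    "target_element": "N"
  },
  "13N": {
    "name": "13N",
    "half_life_min": 9.965,
    "reaction_channel": "16O(p,X)13N",
    "threshold_MeV": 5.55,
    "integrated_xs_mb_MeV": 53.3,
    "target_element": "O"
  },
  "18F": {
    "name": "18F",
    "half_life_min": 109.77,
    "reaction_channel": "18O(p,n)18F",
    "threshold_MeV": 2.57,
    "integrated_xs_mb_MeV": 1130.71,
    "target_element": "O"
  }
}
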