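{
 "calibration": {
  "anchor_response_5nm_pa": 526.0000000004366,
  "ga_loss": 1.8733047075264735,
  "noise_cv": 0.05,
  "seed": 12345
 },
 "network": "bmsc",
 "params": {
  "H": {
   "H1": 0.5,
   "H10": 10.0,
   "H2": 0.4,
   "H3": 2.0087579582797725,
   "H4": 0.6112264746164923,
   "H5": 10.0,
   "H6": 1.3463349723572975,
   "H7": 1.3704674120497935,
   "H8": 1.2256479879013766,
   "H9": 0.23095348828774037
  },
  "d": {
   "d1": 6.872270616449718,
   "d2": 5.0234489951632115,
   "d3": 1.783984552077745,
   "d4": 3.4478743862982366,
   "d5": 5.0232468632590095,
   "d6": 2.793098546189394,
   "d7": 2.570675285515753
  },
  "drug": {},
  "k": {
   "k1": 16.12802441944319,
   "k10": 0.001,
   "k2": 17.34618000879318,
   "k3": 7.946074874181477,
   "k4": 9.411653161485965,
   "k5": 6.296242462655392,
   "k6": 15.512231008545717,
   "k7": 8.186378156638431,
   "k8": 3.49981677335344,
   "k9": 6.140419212717428
  }
 },
 "sdf1_rel_5nm": 0.679251550313848,
 "stiffness_map": {
  "s0": 1.5338020722896386,
  "s_sat": 2.001412832980106
 }
}
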