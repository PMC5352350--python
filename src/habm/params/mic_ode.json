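{
 "calibration": {
  "anchor_adhesion_24h": 0.4700000003657124,
  "anchor_kill_fraction": 0.8920000000000001,
  "ga_loss": 0.6303260855383466,
  "noise_cv": 0.05,
  "seed": 54321,
  "survival_control_144h": 0.9672145335961007
 },
 "network": "mic",
 "params": {
  "H": {
   "H1": 0.3,
   "H10": 0.23624414202640048,
   "H11": 0.8391984472679209,
   "H2": 0.8439392986249632,
   "H3": 10.0,
   "H4": 1.744843999047146,
   "H5": 1.3445833190619254,
   "H6": 1.4709745193976012,
   "H7": 0.2,
   "H8": 0.34690094887065737,
   "H9": 0.2310909631301647
  },
  "d": {
   "d1": 3.630339543422687,
   "d2": 1.1207146264696943,
   "d3": 4.759500647931406,
   "d4": 1.5743531750945954,
   "d5": 2.3150118252154885,
   "d6": 1.9886136735395208,
   "d7": 3.306747066752616,
   "d8": 0.09865614739246162,
   "d9": 0.02134653596134899
  },
  "drug": {
   "D1": [
    0.025102651108707148,
    1.5
   ]
  },
  "k": {
   "k1": 10.261652449270803,
   "k10": 0.0459026625017944,
   "k11": 0.02813643321817847,
   "k2": 1.3282090995630305,
   "k3": 0.001,
   "k4": 16.046862941878004,
   "k5": 6.441175210176035,
   "k6": 13.714131501612037,
   "k7": 4.274746117533119,
   "k8": 5.548967716133668,
   "k9": 4.044948773080692
  }
 }
}
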