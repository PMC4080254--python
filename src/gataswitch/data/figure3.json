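{
  "a1": 731.7409,
  "a2": 856.1247,
  "a3": 1.0,
  "a4": 1.6,
  "a5": 398.9719,
  "a6": 44.8982,
  "a7": 53.0,
  "b1": 18470.6419,
  "b2": 1.0,
  "b3": 37.3615,
  "b4": 942.1939,
  "b5": 55.0375,
  "b6": 53.0,
  "c1": 12391.1968,
  "c2": 1.0,
  "c3": 710.449,
  "c4": 522.4385,
  "c5": 170.0,
  "c6": 1700.0,
  "c7": 1700.0,
  "k1": 0.6931,
  "k2": 1.3863,
  "k3": 0.2888
}
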