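{
 "age_bins": [
  "<8",
  "8-16",
  ">=16"
 ],
 "bin_edges": [
  0.0,
  8.0,
  16.0
 ],
 "counts": {
  "X_X": [
   15,
   30,
   18
  ],
  "DR3_X": [
   24,
   33,
   13
  ],
  "DR4_X": [
   39,
   62,
   18
  ],
  "DR3_DR3": [
   10,
   29,
   2
  ],
  "DR4_DR4": [
   6,
   15,
   11
  ],
  "DR3_DR4": [
   56,
   60,
   10
  ]
 },
 "printed_or": {
  "X_X": [
   0.59,
   0.86,
   2.47
  ],
  "DR3_X": [
   1.06,
   0.84,
   1.24
  ],
  "DR4_X": [
   0.97,
   1.07,
   0.92
  ],
  "DR3_DR3": [
   0.62,
   2.54,
   0.25
  ],
  "DR4_DR4": [
   0.44,
   0.85,
   3.07
  ],
  "DR3_DR4": [
   1.97,
   0.84,
   0.37
  ]
 }
}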