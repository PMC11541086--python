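{
 "class_names": [
  "A",
  "B",
  "C",
  "D"
 ],
 "channel_labels": [
  "Fp1",
  "Fp2",
  "F7",
  "F3",
  "Fz",
  "F4",
  "F8",
  "T7",
  "C3",
  "Cz",
  "C4",
  "T8",
  "P7",
  "P3",
  "Pz",
  "P4",
  "P8",
  "O1",
  "O2"
 ],
 "maps": [
  [
   0.191,
   0.3547,
   -0.0546,
   0.0409,
   0.1637,
   0.2592,
   0.382,
   -0.2729,
   -0.1364,
   0.0,
   0.1364,
   0.2729,
   -0.382,
   -0.2592,
   -0.1637,
   -0.0409,
   0.0546,
   -0.3547,
   -0.191
  ],
  [
   0.3547,
   0.191,
   0.382,
   0.2592,
   0.1637,
   0.0409,
   -0.0546,
   0.2729,
   0.1364,
   0.0,
   -0.1364,
   -0.2729,
   0.0546,
   -0.0409,
   -0.1637,
   -0.2592,
   -0.382,
   -0.191,
   -0.3547
  ],
  [
   0.3684,
   0.3684,
   0.221,
   0.2026,
   0.221,
   0.2026,
   0.221,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   -0.221,
   -0.2026,
   -0.221,
   -0.2026,
   -0.221,
   -0.3684,
   -0.3684
  ],
  [
   -0.0495,
   -0.0495,
   -0.0958,
   0.2592,
   0.4303,
   0.2592,
   -0.0958,
   -0.1771,
   0.1915,
   0.5291,
   0.1915,
   -0.1771,
   -0.2189,
   -0.1092,
   -0.0802,
   -0.1092,
   -0.2189,
   -0.2398,
   -0.2398
  ]
 ]
}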