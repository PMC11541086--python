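{
 "electrodes": [
  "Fp1",
  "Fpz",
  "Fp2",
  "AF7",
  "AF3",
  "AFz",
  "AF4",
  "AF8",
  "F7",
  "F5",
  "F3",
  "F1",
  "Fz",
  "F2",
  "F4",
  "F6"
 ]
}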