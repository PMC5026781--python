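{
 "family": "flanked",
 "params": {
  "g_I": [
   0.1,
   0.05,
   0.02,
   0.01,
   0.005,
   0.002
  ],
  "g_D": [
   0.12,
   0.06,
   0.03,
   0.02,
   0.01,
   0.005
  ]
 }
}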