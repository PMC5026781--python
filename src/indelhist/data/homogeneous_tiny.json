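{
 "family": "homogeneous",
 "params": {
  "g_I": [
   0.2
  ],
  "g_D": [
   0.2
  ]
 }
}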