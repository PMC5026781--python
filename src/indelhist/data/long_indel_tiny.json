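{
 "family": "long_indel",
 "params": {
  "lambda_1": 0.05,
  "mu_1": 0.1,
  "mu": [
   0.1,
   0.03,
   0.01
  ]
 }
}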