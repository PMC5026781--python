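{
 "family": "dawg",
 "params": {
  "lambda_I": 0.1,
  "f_I": [
   0.5,
   0.3,
   0.2
  ],
  "lambda_D": 0.1,
  "f_D": [
   0.5,
   0.3,
   0.2
  ]
 }
}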