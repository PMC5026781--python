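{
 "family": "region_hetero",
 "params": {
  "g_I": [
   0.08,
   0.04
  ],
  "g_D": [
   0.08,
   0.04
  ],
  "regions": [
   {
    "anchor": [
     2,
     3
    ],
    "delta_g_I": [
     0.05,
     0.02
    ],
    "delta_g_D": [
     0.05,
     0.02
    ]
   },
   {
    "anchor": [
     6,
     7
    ],
    "delta_g_I": [
     0.03,
     0.01
    ],
    "delta_g_D": [
     0.03,
     0.01
    ]
   }
  ]
 },
 "regions_initial_state": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8
 ]
}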