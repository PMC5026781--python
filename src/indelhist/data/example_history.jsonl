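{"initial": [1, 2, 3, 4, 5, 6, 7]}
{"type": "D", "xB": 3, "xE": 3}
{"type": "I", "x": 5, "l": 2}
{"type": "D", "xB": 2, "xE": 3}
{"type": "I", "x": 5, "l": 1}
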