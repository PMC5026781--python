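# three-leaf MSA: one column deleted on the branch to A
A: 1 - 3
B: 1 2 3
C: 1 2 3
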