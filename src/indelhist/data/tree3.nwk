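((A:0.2,B:0.2):0.1,C:0.3);
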