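# worked-example pairwise alignment: ancestor [1..7] vs descendant [1,5,6,8,9,10,7]
1 2 3 4 5 6 - - - 7
1 - - - 5 6 8 9 10 7
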