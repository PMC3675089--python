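year,pairs
1992,8
1993,17
1994,17
1995,13
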