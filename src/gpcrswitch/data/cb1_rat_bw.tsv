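helix	first	last	x50
1	112	145	135
2	150	179	164
3	186	221	215
4	230	258	256
5	270	310	287
6	331	368	359
7	372	399	395
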