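helix	first	last	x50
1	8	36	32
2	55	80	69
3	90	125	119
4	135	160	150
5	172	205	186
6	213	250	241
7	258	298	285
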