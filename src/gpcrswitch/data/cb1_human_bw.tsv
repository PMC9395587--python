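helix	first	last	x50
1	111	144	134
2	149	178	163
3	185	220	214
4	229	257	255
5	269	309	286
6	330	367	358
7	371	398	394
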