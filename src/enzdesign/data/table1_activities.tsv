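variant	roche_activity_pct	pnpb_activity_pct
H14G	932.4	20.6
M16T	603.4	19.0
L17G	561	41.4
M16A	476.5	67.3
H14G_R56N	411.1	11.4
H14G_L17A	262.4	0.9
H81S	233.4	1.0
M16A_F214I	187.2	9.2
WT	100	100
M16A_G139F	0	2.7
M16A_H14P	0	0.7
M16A_R56K	0	Na
M16A_I142M	0	Na
M16A_I142Y	0	40.5
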