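receiver	s54_pair	r2r4	r3	input	phosphotransfer	category	sf_subfamily
0	0	0	0	0	0	TR	none
0	0	0	0	0	1	TR	none
0	0	0	0	1	0	OCS	none
0	0	0	0	1	1	TR	none
0	0	0	1	0	0	TR	none
0	0	0	1	0	1	TR	none
0	0	0	1	1	0	OCS	none
0	0	0	1	1	1	TR	none
0	0	1	0	0	0	SF	ECF
0	0	1	0	0	1	SF	ECF
0	0	1	0	1	0	SF	ECF
0	0	1	0	1	1	SF	ECF
0	0	1	1	0	0	SF	RpoD
0	0	1	1	0	1	SF	RpoD
0	0	1	1	1	0	SF	RpoD
0	0	1	1	1	1	SF	RpoD
0	1	0	0	0	0	SF	RpoN
0	1	0	0	0	1	SF	RpoN
0	1	0	0	1	0	SF	RpoN
0	1	0	0	1	1	SF	RpoN
0	1	0	1	0	0	SF	RpoN
0	1	0	1	0	1	SF	RpoN
0	1	0	1	1	0	SF	RpoN
0	1	0	1	1	1	SF	RpoN
0	1	1	0	0	0	SF	RpoN
0	1	1	0	0	1	SF	RpoN
0	1	1	0	1	0	SF	RpoN
0	1	1	0	1	1	SF	RpoN
0	1	1	1	0	0	SF	RpoN
0	1	1	1	0	1	SF	RpoN
0	1	1	1	1	0	SF	RpoN
0	1	1	1	1	1	SF	RpoN
1	0	0	0	0	0	RR	none
1	0	0	0	0	1	RR	none
1	0	0	0	1	0	RR	none
1	0	0	0	1	1	RR	none
1	0	0	1	0	0	RR	none
1	0	0	1	0	1	RR	none
1	0	0	1	1	0	RR	none
1	0	0	1	1	1	RR	none
1	0	1	0	0	0	RR	none
1	0	1	0	0	1	RR	none
1	0	1	0	1	0	RR	none
1	0	1	0	1	1	RR	none
1	0	1	1	0	0	RR	none
1	0	1	1	0	1	RR	none
1	0	1	1	1	0	RR	none
1	0	1	1	1	1	RR	none
1	1	0	0	0	0	RR	none
1	1	0	0	0	1	RR	none
1	1	0	0	1	0	RR	none
1	1	0	0	1	1	RR	none
1	1	0	1	0	0	RR	none
1	1	0	1	0	1	RR	none
1	1	0	1	1	0	RR	none
1	1	0	1	1	1	RR	none
1	1	1	0	0	0	RR	none
1	1	1	0	0	1	RR	none
1	1	1	0	1	0	RR	none
1	1	1	0	1	1	RR	none
1	1	1	1	0	0	RR	none
1	1	1	1	0	1	RR	none
1	1	1	1	1	0	RR	none
1	1	1	1	1	1	RR	none
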