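species	oxygens	t_min	t_max
PC(16:0/20:4)	1	2.8	4.6
PC(16:0/20:4)	2	2.9	4.3
PC(16:0/20:4)	3	1.45	2.3
PE(16:0/20:4)	1	2.79	2.96
PE(16:0/20:4)	2	2.84	3.04
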