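chr1	1000	1015	DEMO_BAT_A	demo
chr1	2000	2020	DEMO_BAT_B	demo
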