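marker	intra_min	intra_max	inter_min	inter_max
V4	0	0.9	0	2.2
V9	0	2.9	0	8.6
ITS1	0	5.1	4.2	59.6
ITS2	0	5.9	1.9	83.7
ITS1-5.8S-ITS2	0	3.6	2.3	44.5
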