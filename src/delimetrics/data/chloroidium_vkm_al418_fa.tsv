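fa	mean_9C	sd_9C	mean_22C	sd_22C	mean_27C	sd_27C
14:0	1.0	0.1	1.2	0.3	1.1	0.1
16:0	20.6	1.5	23.0	1.9	41.8	3.5
16:1 Δ7	1.9	0.6	0.4	0.1	0.2	0.2
16:1 Δ9	0.0	0.0	1.0	0.1	0.3	0.3
16:2 Δ7,10	1.8	0.1	2.7	0.1	0.4	0.2
16:3 Δ7,10,13	6.0	0.9	1.7	0.4	0.1	0.1
18:0	2.4	0.7	0.8	0.6	3.4	1.3
18:1 Δ9	5.7	1.3	7.3	0.1	25.4	3.0
18:1 Δ11	1.3	0.1	2.6	0.3	1.4	0.1
18:2 Δ9,12	17.1	0.9	36.1	2.2	21.2	4.0
18:3 Δ9,12,15	41.6	2.0	22.8	1.4	3.0	1.1
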