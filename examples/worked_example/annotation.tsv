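gene_id	transcript_length	utr5_length	utr3_length
g_m1	1000	180	150
g_m2	1000	140	300
g_m3	1000	110	400
g_m4	1000	120	350
g_mat	1000	90	240
g_emb	1000	160	200
g_b1	1000	50	180
g_b2	1000	100	220
g_b3	1000	101	260
g_b4	1000	130	320
g_b5	1000	200	150
g_b6	1000	150	210
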