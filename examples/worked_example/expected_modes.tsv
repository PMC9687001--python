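gene_id	stage	mode
g_m1	GV	1
g_m2	GV	2
g_m3	GV	3
g_m4	GV	4
g_mat	GV	none
g_emb	GV	none
g_b1	GV	none
g_b2	GV	none
g_b3	GV	none
g_b4	GV	none
g_b5	GV	none
g_b6	GV	none
g_m1	8C	1
g_m2	8C	2
g_m3	8C	3
g_m4	8C	4
g_mat	8C	none
g_emb	8C	none
g_b1	8C	none
g_b2	8C	none
g_b3	8C	none
g_b4	8C	none
g_b5	8C	none
g_b6	8C	none
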