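sample_id	stage	sample_type	fraction	replicate
GV_F1_r1	GV	fraction	1	1
GV_F2_r1	GV	fraction	2	1
GV_F3_r1	GV	fraction	3	1
GV_F4_r1	GV	fraction	4	1
GV_F5_r1	GV	fraction	5	1
GV_F6_r1	GV	fraction	6	1
GV_F7_r1	GV	fraction	7	1
GV_F8_r1	GV	fraction	8	1
GV_F9_r1	GV	fraction	9	1
GV_F10_r1	GV	fraction	10	1
GV_T_r1	GV	transcriptome	NA	1
8C_F1_r1	8C	fraction	1	1
8C_F2_r1	8C	fraction	2	1
8C_F3_r1	8C	fraction	3	1
8C_F4_r1	8C	fraction	4	1
8C_F5_r1	8C	fraction	5	1
8C_F6_r1	8C	fraction	6	1
8C_F7_r1	8C	fraction	7	1
8C_F8_r1	8C	fraction	8	1
8C_F9_r1	8C	fraction	9	1
8C_F10_r1	8C	fraction	10	1
8C_T_r1	8C	transcriptome	NA	1
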