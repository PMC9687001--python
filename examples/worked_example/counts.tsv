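gene_id	GV_F1_r1	GV_F2_r1	GV_F3_r1	GV_F4_r1	GV_F5_r1	GV_F6_r1	GV_F7_r1	GV_F8_r1	GV_F9_r1	GV_F10_r1	GV_T_r1	8C_F1_r1	8C_F2_r1	8C_F3_r1	8C_F4_r1	8C_F5_r1	8C_F6_r1	8C_F7_r1	8C_F8_r1	8C_F9_r1	8C_F10_r1	8C_T_r1
g_m1	5	5	10	20	30	45	60	80	100	120	20	5	5	10	20	30	45	60	80	100	120	20
g_m2	200	200	300	400	500	600	700	800	900	1000	3000	200	200	300	400	500	600	700	800	900	1000	3000
g_m3	450	450	450	450	450	450	450	450	450	450	2500	450	450	450	450	450	450	450	450	450	450	2500
g_m4	100	100	800	700	600	300	200	100	80	60	300	100	100	800	700	600	300	200	100	80	60	300
g_mat	800	800	800	800	800	800	800	800	800	800	800	4	4	4	4	4	4	4	4	4	4	5
g_emb	4	4	4	4	4	4	4	4	4	4	10	800	800	800	800	800	800	800	800	800	800	800
g_b1	60	60	60	60	60	60	60	60	60	60	50	60	60	60	60	60	60	60	60	60	60	50
g_b2	120	120	120	120	120	120	120	120	120	120	100	120	120	120	120	120	120	120	120	120	120	100
g_b3	240	240	240	240	240	240	240	240	240	240	200	240	240	240	240	240	240	240	240	240	240	200
g_b4	480	480	480	480	480	480	480	480	480	480	400	480	480	480	480	480	480	480	480	480	480	400
g_b5	720	720	720	720	720	720	720	720	720	720	600	720	720	720	720	720	720	720	720	720	720	600
g_b6	6821	6821	6016	6006	5996	6181	6166	6146	6046	5946	2020	6821	6821	6016	6006	5996	6181	6166	6146	6046	5946	2025
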