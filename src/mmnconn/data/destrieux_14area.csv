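roi_id,roi_name,area
1,L_G_and_S_frontomargin,LVPF
2,L_G_and_S_occipital_inf,LO
3,L_G_and_S_paracentral,LC
4,L_G_and_S_subcentral,LC
5,L_G_and_S_transv_frontopol,LVPF
6,L_G_and_S_cingul-Ant,LCing
7,L_G_and_S_cingul-Mid-Ant,LCing
8,L_G_and_S_cingul-Mid-Post,LCing
9,L_G_cingul-Post-dorsal,LCing
10,L_G_cingul-Post-ventral,LCing
11,L_G_cuneus,LO
12,L_G_front_inf-Opercular,LVPF
13,L_G_front_inf-Orbital,LVPF
14,L_G_front_inf-Triangul,LVPF
15,L_G_front_middle,LDPF
16,L_G_front_sup,LDPF
17,L_G_Ins_lg_and_S_cent_ins,LT
18,L_G_insular_short,LT
19,L_G_occipital_middle,LO
20,L_G_occipital_sup,LO
21,L_G_oc-temp_lat-fusifor,LT
22,L_G_oc-temp_med-Lingual,LO
23,L_G_oc-temp_med-Parahip,LT
24,L_G_orbital,LVPF
25,L_G_pariet_inf-Angular,LP
26,L_G_pariet_inf-Supramar,LP
27,L_G_parietal_sup,LP
28,L_G_postcentral,LC
29,L_G_precentral,LC
30,L_G_precuneus,LP
31,L_G_rectus,LVPF
32,L_G_subcallosal,LVPF
33,L_G_temp_sup-G_T_transv,LT
34,L_G_temp_sup-Lateral,LT
35,L_G_temp_sup-Plan_polar,LT
36,L_G_temp_sup-Plan_tempo,LT
37,L_G_temporal_inf,LT
38,L_G_temporal_middle,LT
39,L_Lat_Fis-ant-Horizont,LVPF
40,L_Lat_Fis-ant-Vertical,LVPF
41,L_Lat_Fis-post,LT
42,L_Pole_occipital,LO
43,L_Pole_temporal,LT
44,L_S_calcarine,LO
45,L_S_central,LC
46,L_S_cingul-Marginalis,LCing
47,L_S_circular_insula_ant,LT
48,L_S_circular_insula_inf,LT
49,L_S_circular_insula_sup,LT
50,L_S_collat_transv_ant,LT
51,L_S_collat_transv_post,LO
52,L_S_front_inf,LDPF
53,L_S_front_middle,LDPF
54,L_S_front_sup,LDPF
55,L_S_interm_prim-Jensen,LP
56,L_S_intrapariet_and_P_trans,LP
57,L_S_oc_middle_and_Lunatus,LO
58,L_S_oc_sup_and_transversal,LO
59,L_S_occipital_ant,LO
60,L_S_oc-temp_lat,LT
61,L_S_oc-temp_med_and_Lingual,LO
62,L_S_orbital_lateral,LVPF
63,L_S_orbital_med-olfact,LVPF
64,L_S_orbital-H_Shaped,LVPF
65,L_S_parieto_occipital,LP
66,L_S_pericallosal,LCing
67,L_S_postcentral,LC
68,L_S_precentral-inf-part,LC
69,L_S_precentral-sup-part,LC
70,L_S_suborbital,LVPF
71,L_S_subparietal,LP
72,L_S_temporal_inf,LT
73,L_S_temporal_sup,LT
74,L_S_temporal_transverse,LT
75,R_G_and_S_frontomargin,RVPF
76,R_G_and_S_occipital_inf,RO
77,R_G_and_S_paracentral,RC
78,R_G_and_S_subcentral,RC
79,R_G_and_S_transv_frontopol,RVPF
80,R_G_and_S_cingul-Ant,RCing
81,R_G_and_S_cingul-Mid-Ant,RCing
82,R_G_and_S_cingul-Mid-Post,RCing
83,R_G_cingul-Post-dorsal,RCing
84,R_G_cingul-Post-ventral,RCing
85,R_G_cuneus,RO
86,R_G_front_inf-Opercular,RVPF
87,R_G_front_inf-Orbital,RVPF
88,R_G_front_inf-Triangul,RVPF
89,R_G_front_middle,RDPF
90,R_G_front_sup,RDPF
91,R_G_Ins_lg_and_S_cent_ins,RT
92,R_G_insular_short,RT
93,R_G_occipital_middle,RO
94,R_G_occipital_sup,RO
95,R_G_oc-temp_lat-fusifor,RT
96,R_G_oc-temp_med-Lingual,RO
97,R_G_oc-temp_med-Parahip,RT
98,R_G_orbital,RVPF
99,R_G_pariet_inf-Angular,RP
100,R_G_pariet_inf-Supramar,RP
101,R_G_parietal_sup,RP
102,R_G_postcentral,RC
103,R_G_precentral,RC
104,R_G_precuneus,RP
105,R_G_rectus,RVPF
106,R_G_subcallosal,RVPF
107,R_G_temp_sup-G_T_transv,RT
108,R_G_temp_sup-Lateral,RT
109,R_G_temp_sup-Plan_polar,RT
110,R_G_temp_sup-Plan_tempo,RT
111,R_G_temporal_inf,RT
112,R_G_temporal_middle,RT
113,R_Lat_Fis-ant-Horizont,RVPF
114,R_Lat_Fis-ant-Vertical,RVPF
115,R_Lat_Fis-post,RT
116,R_Pole_occipital,RO
117,R_Pole_temporal,RT
118,R_S_calcarine,RO
119,R_S_central,RC
120,R_S_cingul-Marginalis,RCing
121,R_S_circular_insula_ant,RT
122,R_S_circular_insula_inf,RT
123,R_S_circular_insula_sup,RT
124,R_S_collat_transv_ant,RT
125,R_S_collat_transv_post,RO
126,R_S_front_inf,RDPF
127,R_S_front_middle,RDPF
128,R_S_front_sup,RDPF
129,R_S_interm_prim-Jensen,RP
130,R_S_intrapariet_and_P_trans,RP
131,R_S_oc_middle_and_Lunatus,RO
132,R_S_oc_sup_and_transversal,RO
133,R_S_occipital_ant,RO
134,R_S_oc-temp_lat,RT
135,R_S_oc-temp_med_and_Lingual,RO
136,R_S_orbital_lateral,RVPF
137,R_S_orbital_med-olfact,RVPF
138,R_S_orbital-H_Shaped,RVPF
139,R_S_parieto_occipital,RP
140,R_S_pericallosal,RCing
141,R_S_postcentral,RC
142,R_S_precentral-inf-part,RC
143,R_S_precentral-sup-part,RC
144,R_S_suborbital,RVPF
145,R_S_subparietal,RP
146,R_S_temporal_inf,RT
147,R_S_temporal_sup,RT
148,R_S_temporal_transverse,RT
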