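drug	gene	total	mut_res	n_res	f_res	mut_sen	n_sen	f_sen	diff
17AAG	SPEN	447	21	97	0.216	38	350	0.109	0.107
AEW541	MLL3	447	128	430	0.298	1	17	0.059	0.239
AZD0530	MAP3K1	448	339	434	0.781	8	14	0.571	0.21
AZD6244	TP53	447	249	382	0.652	30	65	0.462	0.19
Erlotinib	TTN	447	321	438	0.733	3	9	0.333	0.4
Irinotecan	KRAS	279	30	97	0.309	33	182	0.181	0.128
L685458	KRAS	435	90	423	0.213	0	12	0	0.213
LBW242	MLL3	435	125	423	0.296	1	12	0.083	0.213
Lapatinib	MSH3	447	148	434	0.341	2	13	0.154	0.187
Nilotinib	LRP1B	370	109	358	0.304	0	12	0	0.304
Nutlin3	TP53	448	280	446	0.628	0	2	0	0.628
PD0325901	TP53	448	223	330	0.676	57	118	0.483	0.193
PD0332991	MAP3K1	384	295	379	0.778	2	5	0.4	0.378
PF2341066	PDE4DIP	448	241	436	0.553	2	12	0.167	0.386
PHA665752	NCOA3	447	200	444	0.45	0	3	0	0.45
PLX4720	TP53	440	274	431	0.636	1	9	0.111	0.525
Paclitaxel	GPR112	447	54	71	0.761	241	376	0.641	0.12
Panobinostat	HSPA4	444	2	4	0.5	4	440	0.009	0.491
RAF265	KRAS	408	81	355	0.228	4	53	0.075	0.153
Sorafenib	CREB3L2	447	226	439	0.515	1	8	0.125	0.39
TAE684	CSMD3	448	105	416	0.252	2	32	0.062	0.19
TKI258	AAK1	448	241	441	0.546	1	7	0.143	0.403
Topotecan	KRAS	448	60	220	0.273	32	228	0.14	0.133
ZD6474	CREB3L2	440	224	430	0.521	2	10	0.2	0.321
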