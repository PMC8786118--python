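site_id	group	display_offset	ref	alt	af_E	af_LA	af_A	af_W	mi_before	mi_after	pam_after
5	increase_mismatches	16	TAC	T	0.043	0.037	0.113	0.070	4/0	4/2	.
75	increase_mismatches	18	C	T	0	0.006	0.031	0.009	2/1	3/1	.
75	increase_mismatches	14	G	C	0	0	0.014	0.004	2/1	3/1	.
82	increase_mismatches	20	C	T	0.810	0.878	0.629	0.790	3/1	4/1	.
44	decrease_mismatches	9	T	C	.	.	.	.	6/0	5/0	.
73	decrease_mismatches	2	A	G	.	.	.	.	6/0	5/0	.
146	decrease_mismatches	13	G	A	.	.	.	.	5/1	4/1	.
223	decrease_mismatches	14	C	A	.	.	.	.	4/2	3/2	.
227	decrease_mismatches	5	G	A	.	.	.	.	5/2	4/2	.
265	decrease_mismatches	3	T	A	.	.	.	.	6/2	5/2	.
9	pam_disrupted	22	C	T	0.223	0.177	0.027	0.116	.	.	CAG
18	pam_disrupted	22	C	T	0.001	0.004	0.061	0.017	.	.	CAG
59	pam_disrupted	23	C	A	0	0.010	0.092	0.026	.	.	AGT
97	pam_disrupted	22	G	A	0	0.011	0	0.007	.	.	AAG
123	pam_disrupted	23	C	T	0	0.003	0.029	0.008	.	.	CAG
173	pam_disrupted	22	G	A	0	0.006	0.039	0.011	.	.	TAG
273	pam_created	23	T	G	0.160	0.160	0.423	0.248	.	.	AGG
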