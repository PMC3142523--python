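locus	length_bp	chromosome	arm	rel_dist_centromere	region	evo_rate	alpha	prop_variable	td_supermatrix	td_bucky
LOC_Os01g01790	860	3	short	0.976	telomeric	1.687	0.527	0.313	0.152	0.246
LOC_Os01g09300	861	3	short	0.722	telomeric	0.883	0.342	0.285	0.207	0.272
LOC_Os01g11070	1050	3	short	0.652	centromeric	1.033	0.380	0.305	0.299	0.264
LOC_Os01g13200	897	3	short	0.568	centromeric	0.659	0.270	0.220	0.140	0.173
LOC_Os01g19470	942	3	short	0.352	centromeric	0.906	0.687	0.321	0.104	0.109
LOC_Os01g21160	1017	3	short	0.307	centromeric	1.596	0.475	0.393	0.236	0.291
LOC_Os01g24680	1014	3	short	0.184	centromeric	0.875	0.805	0.260	0.371	0.395
LOC_Os01g37560	1005	3	long	0.160	centromeric	1.060	0.392	0.310	0.158	0.201
LOC_Os01g39310	945	3	long	0.202	centromeric	0.989	0.328	0.290	0.108	0.243
LOC_Os01g48720	939	3	long	0.417	centromeric	1.252	0.805	0.399	0.203	0.288
LOC_Os01g53720	1101	3	long	0.526	centromeric	0.921	0.521	0.320	0.170	0.170
LOC_Os01g55530	1068	3	long	0.567	centromeric	0.890	0.426	0.309	0.131	0.074
LOC_Os01g56630	915	3	long	0.592	centromeric	0.731	0.504	0.312	0.105	0.163
LOC_Os01g60230	999	3	long	0.673	centromeric	0.929	0.355	0.283	0.202	0.159
LOC_Os01g61720	935	3	long	0.705	telomeric	1.131	0.385	0.328	0.080	0.098
LOC_Os01g62900	951	3	long	0.732	telomeric	0.897	0.241	0.257	0.113	0.290
LOC_Os01g67220	1101	3	long	0.827	telomeric	1.303	0.414	0.322	0.238	0.245
LOC_Os01g68770	998	3	long	0.862	telomeric	1.307	0.631	0.278	0.287	0.272
LOC_Os01g70670	883	3	long	0.898	telomeric	0.899	0.404	0.310	0.105	0.210
LOC_Os01g72220	1131	3	long	0.933	telomeric	0.974	0.253	0.255	0.279	0.385
LOC_Os01g73790	966	3	long	0.965	telomeric	0.850	0.689	0.180	0.227	0.244
eIFiso4E	630	1	long	NA	centromeric	0.952	1.004	0.128	0.221	0.430
CRTISO	529	4	long	NA	NA	1.165	0.807	0.163	0.347	0.329
PinA	456	5	short	NA	NA	1.375	0.243	0.189	0.506	0.382
PinB	453	5	short	NA	NA	2.411	0.264	0.218	0.297	0.303
PSY2	461	NA	NA	NA	NA	0.978	0.648	0.150	0.246	0.372
MATK	1545	chloroplast	NA	NA	NA	0.462	0.373	0.177	0.128	0.217
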