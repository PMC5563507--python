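chr1	54309	54618	Irf4_t00001	0	.	0	-1	40.15766021611864	154
chr1	154869	155092	Irf4_t00002	0	.	0	-1	61.90023358840241	111
chr1	301571	302054	Irf4_t00003	0	.	0	-1	15.750795122756813	241
chr1	421536	421877	Irf4_t00004	0	.	0	-1	23.15731095499593	170
chr1	633185	633520	Irf4_t00005	0	.	0	-1	61.82615806249784	167
chr1	712740	713219	Irf4_t00006	0	.	0	-1	76.00540873382757	239
chr1	769135	769344	Irf4_t00007	0	.	0	-1	33.80903902730415	104
chr1	793778	794103	Irf4_d00005	0	.	0	-1	28.08284751068139	162
chr1	993715	994024	Irf4_t00008	0	.	0	-1	95.55519969799975	154
chr1	1144522	1145013	Irf4_t00009	0	.	0	-1	91.10491310720009	245
chr1	1222386	1222649	Irf4_t00010	0	.	0	-1	78.84664038660733	131
chr1	1354700	1355017	Irf4_t00011	0	.	0	-1	38.49183953350472	158
chr1	1411192	1411405	Irf4_t00012	0	.	0	-1	43.811093843941755	106
chr1	1524461	1524928	Irf4_t00013	0	.	0	-1	67.93128131118536	233
chr1	1900344	1900661	Irf4_d00012	0	.	0	-1	63.12716898724321	158
chr1	2145268	2145695	Irf4_d00018	0	.	0	-1	6.963214655820705	213
chr1	2203590	2203877	Irf4_d00009	0	.	0	-1	18.232282855698912	143
chr1	2418319	2418706	Irf4_d00003	0	.	0	-1	23.816137611958755	193
chr1	2589361	2589754	Irf4_d00013	0	.	0	-1	12.128528937193046	196
chr1	2735401	2735780	Irf4_d00010	0	.	0	-1	7.633467858994344	189
chr1	2738589	2738980	Irf4_d00011	0	.	0	-1	99.76463841407893	195
chr2	19853	20210	Irf4_t00014	0	.	0	-1	26.347731229350348	178
chr2	221917	222342	Irf4_d00007	0	.	0	-1	71.3097890560048	212
chr2	240190	240631	Irf4_t00015	0	.	0	-1	18.65175185130757	220
chr2	486491	486726	Irf4_t00016	0	.	0	-1	95.51031930257349	117
chr2	793233	793536	Irf4_t00017	0	.	0	-1	24.25812385720008	151
chr2	969002	969389	Irf4_t00018	0	.	0	-1	37.340720022720134	193
chr2	1104845	1105174	Irf4_t00019	0	.	0	-1	95.91870253551158	164
chr2	1137778	1138003	Irf4_t00020	0	.	0	-1	5.1181645283869805	112
chr2	1221115	1221424	Irf4_t00021	0	.	0	-1	5.56851838509121	154
chr2	1280536	1280887	Irf4_t00022	0	.	0	-1	81.16281701702036	175
chr2	1449746	1449955	Irf4_t00023	0	.	0	-1	20.84598689476755	104
chr2	1520794	1521261	Irf4_t00024	0	.	0	-1	70.4302332961192	233
chr2	1735569	1735978	Irf4_d00001	0	.	0	-1	54.31106547051163	204
chr2	2053525	2053848	Irf4_d00016	0	.	0	-1	47.91044429550329	161
chr2	2066441	2066826	Irf4_d00020	0	.	0	-1	73.99492039195397	192
chr2	2147373	2147606	Irf4_d00019	0	.	0	-1	98.31282025246877	116
chr2	2180152	2180611	Irf4_d00015	0	.	0	-1	29.788373382683748	229
chr2	2271637	2271874	Irf4_d00008	0	.	0	-1	12.17003054845234	118
chr2	2636276	2636585	Irf4_d00006	0	.	0	-1	59.881504182022304	154
chr2	2673514	2673903	Irf4_d00014	0	.	0	-1	86.58653449917203	194
chr2	2855888	2856111	Irf4_d00004	0	.	0	-1	65.0490936259728	111
chr2	2890781	2891186	Irf4_d00002	0	.	0	-1	85.7404149873552	202
chr2	2966867	2967248	Irf4_d00017	0	.	0	-1	15.460131077136738	190
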