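chr1	89037	89378	Junb_t00001	0	.	0	-1	9.412645162625296	170
chr1	107291	107524	Junb_t00002	0	.	0	-1	97.61516606735893	116
chr1	297928	298379	Junb_t00003	0	.	0	-1	12.8888242463071	225
chr1	320339	320592	Junb_t00004	0	.	0	-1	49.99895748704968	126
chr1	865440	865733	Junb_t00005	0	.	0	-1	76.08868349374106	146
chr1	925543	925878	Junb_d00015	0	.	0	-1	40.129842467501824	167
chr1	1164987	1165444	Junb_t00006	0	.	0	-1	88.33027797322754	228
chr1	1220556	1220873	Junb_t00007	0	.	0	-1	68.45748978785417	158
chr1	1227633	1227928	Junb_t00008	0	.	0	-1	38.59120372933417	147
chr1	1262432	1262835	Junb_t00009	0	.	0	-1	85.37862837555139	201
chr1	1364898	1365269	Junb_t00010	0	.	0	-1	99.17199240897979	185
chr1	1443442	1443669	Junb_t00011	0	.	0	-1	24.79553049551263	113
chr1	1616896	1617233	Junb_t00012	0	.	0	-1	97.84231829995404	168
chr1	1717217	1717608	Junb_d00009	0	.	0	-1	84.57786161728272	195
chr1	1757729	1758146	Junb_d00014	0	.	0	-1	96.53119764143626	208
chr1	1980453	1980684	Junb_d00008	0	.	0	-1	70.34360023771018	115
chr1	2236805	2237212	Junb_d00001	0	.	0	-1	98.57423465027999	203
chr1	2441326	2441803	Junb_d00003	0	.	0	-1	98.13134872431749	238
chr1	2492453	2492670	Junb_d00004	0	.	0	-1	26.218201304603113	108
chr1	2583302	2583601	Junb_d00007	0	.	0	-1	71.8349285667295	149
chr1	2901065	2901274	Junb_d00019	0	.	0	-1	16.998013562368747	104
chr1	2955764	2956143	Junb_d00013	0	.	0	-1	12.79151351060902	189
chr2	120603	120904	Junb_t00013	0	.	0	-1	15.991777504060957	150
chr2	253968	254405	Junb_t00014	0	.	0	-1	88.84345503843832	218
chr2	510283	510706	Junb_t00015	0	.	0	-1	8.208598328786058	211
chr2	588431	588882	Junb_t00016	0	.	0	-1	66.1264627057883	225
chr2	808936	809319	Junb_t00017	0	.	0	-1	35.243928260483074	191
chr2	973165	973632	Junb_t00018	0	.	0	-1	38.235735615768	233
chr2	1145708	1145927	Junb_t00019	0	.	0	-1	80.94580354896024	109
chr2	1176115	1176446	Junb_t00020	0	.	0	-1	61.483869439217614	165
chr2	1236509	1236818	Junb_t00021	0	.	0	-1	76.01833256262152	154
chr2	1306680	1306979	Junb_t00022	0	.	0	-1	97.58383311119874	149
chr2	1363362	1363615	Junb_t00023	0	.	0	-1	48.8633262920746	126
chr2	1377666	1377979	Junb_t00024	0	.	0	-1	99.04190108398438	156
chr2	1557406	1557773	Junb_t00025	0	.	0	-1	68.81897854284796	183
chr2	1589789	1590114	Junb_t00026	0	.	0	-1	37.88472036290835	162
chr2	1847537	1847954	Junb_d00017	0	.	0	-1	29.63313480820115	208
chr2	2206884	2207281	Junb_d00002	0	.	0	-1	27.411463096727964	198
chr2	2228276	2228735	Junb_d00006	0	.	0	-1	17.74264083215904	229
chr2	2512173	2512464	Junb_d00018	0	.	0	-1	16.646796914695972	145
chr2	2536937	2537264	Junb_d00005	0	.	0	-1	24.92634286817869	163
chr2	2734924	2735375	Junb_d00016	0	.	0	-1	15.080289140506075	225
chr2	2756741	2757226	Junb_d00012	0	.	0	-1	9.021252574734266	242
chr2	2875558	2875777	Junb_d00020	0	.	0	-1	17.263511662921292	109
chr2	2902534	2902767	Junb_d00010	0	.	0	-1	12.671999518612882	116
chr2	2924050	2924527	Junb_d00011	0	.	0	-1	39.89425477657238	238
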