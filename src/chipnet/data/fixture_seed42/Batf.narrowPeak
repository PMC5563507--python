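chr1	212491	212756	Batf_t00001	0	.	0	-1	86.03018615093785	132
chr1	321209	321666	Batf_t00002	0	.	0	-1	9.99737167343958	228
chr1	429854	430213	Batf_t00003	0	.	0	-1	11.280071762045806	179
chr1	665837	666324	Batf_d00017	0	.	0	-1	68.12120357109274	243
chr1	683200	683671	Batf_t00004	0	.	0	-1	73.81370208377409	235
chr1	788723	788984	Batf_t00005	0	.	0	-1	10.294141247450256	130
chr1	838410	838683	Batf_t00006	0	.	0	-1	66.02828064070003	136
chr1	987401	987730	Batf_t00007	0	.	0	-1	58.1598679395949	164
chr1	1083846	1084141	Batf_t00008	0	.	0	-1	67.53830234445701	147
chr1	1115967	1116396	Batf_t00009	0	.	0	-1	97.78918810504253	214
chr1	1161277	1161768	Batf_t00010	0	.	0	-1	29.0375263109205	245
chr1	1210367	1210678	Batf_t00011	0	.	0	-1	19.371964548510626	155
chr1	1317148	1317507	Batf_t00012	0	.	0	-1	85.22598468831907	179
chr1	1333109	1333400	Batf_t00013	0	.	0	-1	46.52272920143677	145
chr1	1740917	1741220	Batf_d00006	0	.	0	-1	40.64279314123097	151
chr1	1817688	1818015	Batf_d00020	0	.	0	-1	12.455127981335295	163
chr1	1864069	1864440	Batf_d00005	0	.	0	-1	67.73652573638225	185
chr1	1919739	1920108	Batf_d00013	0	.	0	-1	8.981144931200173	184
chr1	2052491	2052848	Batf_d00016	0	.	0	-1	81.42658271726982	178
chr1	2091321	2091526	Batf_d00003	0	.	0	-1	61.327491078136035	102
chr1	2171910	2172335	Batf_d00001	0	.	0	-1	28.616847541407626	212
chr1	2317836	2318311	Batf_d00002	0	.	0	-1	25.57955939534117	237
chr1	2575865	2576088	Batf_d00004	0	.	0	-1	7.206653017596976	111
chr1	2617410	2617685	Batf_d00015	0	.	0	-1	88.87745477075626	137
chr1	2679847	2680224	Batf_d00014	0	.	0	-1	49.04660854749925	188
chr1	2980988	2981479	Batf_d00007	0	.	0	-1	47.57530959382595	245
chr2	604687	604908	Batf_t00014	0	.	0	-1	81.44646974503023	110
chr2	641784	642015	Batf_t00015	0	.	0	-1	17.614718516662734	115
chr2	684934	685287	Batf_t00016	0	.	0	-1	80.46490322680424	176
chr2	738810	739053	Batf_t00017	0	.	0	-1	56.60277127747139	121
chr2	757613	758002	Batf_t00018	0	.	0	-1	46.46744608028288	194
chr2	1091963	1092250	Batf_t00019	0	.	0	-1	47.23669678825465	143
chr2	1684914	1685401	Batf_d00012	0	.	0	-1	83.85818531760648	243
chr2	1977162	1977561	Batf_d00018	0	.	0	-1	51.398011571626796	199
chr2	2132302	2132767	Batf_d00009	0	.	0	-1	83.43406124797468	232
chr2	2283006	2283381	Batf_d00008	0	.	0	-1	86.47971758076294	187
chr2	2474415	2474756	Batf_d00011	0	.	0	-1	86.49193694062004	170
chr2	2535626	2535879	Batf_d00010	0	.	0	-1	42.236031903055476	126
chr2	2757150	2757433	Batf_d00019	0	.	0	-1	69.27642427163339	141
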