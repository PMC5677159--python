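sample	chrom	cg_sites	mcg	mcg_pct	chg_sites	mchg	mchg_pct	chh_sites	mchh	mchh_pct	total_c	total_mc	total_pct
Gui99	Chr1	3657714	1496039	40.9	3228108	1040813	32.24	11616288	1936072	16.67	18502110	4472924	24.18
Gui99	Chr2	2905484	1071684	36.88	2636260	749393	28.43	9679734	1384263	14.30	15221478	3205340	21.06
Gui99	Chr3	3021244	1140894	37.76	2724050	777474	28.54	9801969	1492353	15.23	15547263	3410721	21.94
Gui99	Chr4	3053058	1174319	38.46	2679200	844076	31.50	9616649	1274372	13.25	15348907	3292767	21.45
Gui99	Chr5	2539476	1177823	46.38	2218968	835699	37.66	8104757	1304133	16.09	12863201	3317655	25.79
Gui99	Chr6	2594974	1072883	41.34	2295932	764712	33.31	8425977	1269531	15.07	13316883	3107126	23.33
Gui99	Chr7	2444714	936023	38.29	2158950	661921	30.66	8021141	1075987	13.41	12624805	2673931	21.18
Gui99	Chr8	2314860	1003047	43.33	2061584	722042	35.02	7690127	1132860	14.73	12066571	2857949	23.68
Gui99	Chr9	1910938	870619	45.56	1666110	625696	37.55	6205602	984400	15.86	9782650	2480715	25.36
Gui99	Chr10	1928208	799691	41.47	1693122	578771	34.18	6263446	863446	13.79	9884776	2241908	22.68
Gui99	Chr11	2280308	888872	38.98	2060694	645369	31.32	7836803	946497	12.08	12177805	2480738	20.37
Gui99	Chr12	2166398	812002	37.48	1958940	587153	29.97	7452589	881038	11.82	11577927	2280193	19.69
Gui99	Total	30817376	12443896	40.57	27381918	8833119	32.53	100715082	14544952	14.36	158914376	35821967	22.56
fsv1	Chr1	3657714	1474245	40.3	3228108	1011674	31.34	11616288	1825143	15.71	18502110	4311062	23.30
fsv1	Chr2	2905484	1048880	36.10	2636260	724200	27.47	9679734	1303258	13.46	15221478	3076338	20.21
fsv1	Chr3	3021244	1118989	37.04	2724050	752182	27.61	9801969	1405329	14.34	15547263	3276500	21.07
fsv1	Chr4	3053058	1149040	37.64	2679200	814586	30.40	9616649	1193163	12.41	15348907	3156789	20.57
fsv1	Chr5	2539476	1157514	45.58	2218968	812578	36.62	8104757	1221512	15.07	12863201	3191604	24.81
fsv1	Chr6	2594974	1051016	40.50	2295932	739905	32.23	8425977	1189074	14.11	13316883	2979995	22.38
fsv1	Chr7	2444714	919772	37.62	2158950	642605	29.76	8021141	1010426	12.60	12624805	2572803	20.38
fsv1	Chr8	2314860	984233	42.52	2061584	699367	33.92	7690127	1060929	13.80	12066571	2744529	22.74
fsv1	Chr9	1910938	856750	44.83	1666110	609409	36.58	6205602	918688	14.80	9782650	2384847	24.38
fsv1	Chr10	1928208	783499	40.63	1693122	561018	33.14	6263446	810199	12.94	9884776	2154716	21.80
fsv1	Chr11	2280308	870924	38.19	2060694	624862	30.32	7836803	884087	11.28	12177805	2379873	19.54
fsv1	Chr12	2166398	795721	36.73	1958940	565231	28.85	7452589	823245	11.05	11577927	2184197	18.87
fsv1	Total	30817376	12210583	39.81	27381918	8557617	31.52	100715082	13645053	13.46	158914376	34413253	21.67
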