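gene	H1	H2	H3	H4	H5	H6	L1	L2	L3	L4	L5	L6
g01	5000	5200	4800	5100	4900	5030	1000	1100	900	1050	950	1020
g02	1300	1320	1280	1310	1290	1305	1000	1010	990	1005	995	1002
g03	2	4	1	5	3	6	3	1	5	2	6	4
g04	2000	2000	2000	2000	2000	2000	2000	2000	2000	2000	2000	2000
g05	1500	1350	1650	1425	1575	1470	1485	1635	1365	1545	1440	1590
g06	980	1040	950	1025	975	1010	4900	5150	4750	5050	4850	4975
g07	3000	3300	2700	3150	2850	3075	2955	3225	2790	3090	2895	3165
g08	800	801	799	802	800	801	799	800	802	801	799	800
g09	1200	1320	1080	1260	1140	1230	1212	1104	1284	1152	1272	1092
g10	700	770	630	742	665	721	707	644	756	672	735	658
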