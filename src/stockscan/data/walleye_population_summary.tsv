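id	name	state	drainage	latitude	longitude	n_sampled	n_genotyped	ne	ne_ci_low	ne_ci_high	ar	ho	he	fis	coancestry
1	Delavan Lake	Wisconsin	Rock River	42.58	-88.63	48	48	154	153	155	1.584	0.165	0.167	0.016	22.662
2	Wolf River	Wisconsin	Lake Michigan	44.36	-88.69	47	41	1466	1388	1553	1.616	0.184	0.170	-0.052	22.175
3	Lake Wisconsin	Wisconsin	Wisconsin River	43.38	-89.58	48	45	1186	1148	1227	1.643	0.171	0.176	0.027	21.940
4	Medicine Lake	Wisconsin	Wisconsin River	45.81	-89.13	47	47	1471	1409	1539	1.592	0.165	0.166	0.005	22.244
5	Willow Flowage	Wisconsin	Wisconsin River	45.71	-89.87	48	48	19781	12866	42739	1.628	0.167	0.173	0.040	21.442
6	Kawaguesaga Lake	Wisconsin	Wisconsin River	45.86	-89.74	48	42	3257	2968	3608	1.623	0.169	0.172	0.008	21.506
7	Big Arbor Vitae Lake	Wisconsin	Wisconsin River	45.93	-89.65	48	44	974	946	1003	1.625	0.168	0.172	0.034	21.422
8	Escanaba Lake	Wisconsin	Chippewa River	46.06	-89.59	48	44	480	473	487	1.614	0.175	0.169	-0.020	21.601
9	Sanford Lake	Wisconsin	Chippewa River	46.18	-89.69	48	44	55	55	55	1.528	0.167	0.159	-0.036	23.388
10	Manitowish Lake	Wisconsin	Chippewa River	46.11	-89.85	47	35	1372	1294	1461	1.621	0.171	0.172	0.017	21.446
11	Turtle Flambeau Flowage	Wisconsin	Chippewa River	46.06	-90.13	47	38	488	479	497	1.641	0.171	0.172	0.006	21.185
12	Chippewa Flowage	Wisconsin	Chippewa River	45.90	-91.09	47	43	889	864	916	1.633	0.173	0.171	-0.005	21.207
13	Eau Claire River	Wisconsin	Chippewa River	44.80	-91.50	47	47	937	910	964	1.568	0.159	0.160	0.008	22.897
14	Lake Millicent	Wisconsin	Lake Superior	46.53	-91.37	48	32	226	223	230	1.605	0.173	0.165	-0.032	21.627
15	St. Louis River	Border water	Lake Superior	46.65	-92.21	32	30	132	131	133	1.596	0.164	0.166	0.009	23.334
16	Pike River	Minnesota	Hudson Bay	47.59	-92.39	32	28	6772	4511	13570	1.493	0.141	0.143	0.012	23.278
17	Sarah Lake	Minnesota	Mississippi River	44.15	-95.77	32	30	943	894	999	1.582	0.164	0.163	-0.005	22.264
18	Lake Koronis	Minnesota	Mississippi River	45.33	-94.70	32	17	94	92	95	1.566	0.155	0.153	-0.017	22.112
19	Mille Lacs	Minnesota	Mississippi River	46.25	-93.67	32	29	5671	3997	9748	1.502	0.150	0.146	-0.020	23.721
20	Pine River	Minnesota	Mississippi River	46.70	-94.39	32	30	365	356	374	1.538	0.162	0.155	-0.031	22.610
21	Cut Foot Sioux	Minnesota	Mississippi River	47.50	-94.09	32	25	622	590	658	1.515	0.148	0.146	-0.017	22.730
22	Otter Tail Lake	Minnesota	Hudson Bay	46.41	-95.66	32	23	Infinite	Infinite	Infinite	1.554	0.158	0.156	-0.013	22.196
23	Red Lake	Minnesota	Hudson Bay	47.91	-95.04	32	29	103	102	104	1.506	0.153	0.148	-0.025	23.702
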