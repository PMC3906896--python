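# SYNTHETIC directional amino-acid exchangeability matrix (rows =
# ancestral state, columns = derived state). Placeholder with the
# published-matrix schema; replace with real EX values for inference.
from\to	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	1.0000	0.5904	0.3913	0.2889	0.3784	0.6164	0.5225	0.3611	0.3539	0.5376	0.6379	0.2698	0.9139	0.6483	0.4679	0.7657	0.7178	0.5529	0.3442	0.6508
C	0.4325	1.0000	0.2813	0.2649	0.7579	0.5058	0.4123	0.7285	0.3853	0.6731	0.6768	0.3458	0.6396	0.3229	0.3019	0.3247	0.3791	0.8603	0.7327	0.7492
D	0.4212	0.1596	1.0000	0.7713	0.2691	0.2784	0.5728	0.3510	0.4476	0.3338	0.2617	0.5983	0.4306	0.4163	0.4523	0.3054	0.4749	0.1286	0.2372	0.2081
E	0.2981	0.3240	0.7729	1.0000	0.1076	0.3040	0.4666	0.1239	0.6076	0.0954	0.3417	0.7493	0.4352	0.5174	0.4391	0.5392	0.4181	0.1859	0.3610	0.3299
F	0.5411	0.9389	0.1580	0.2280	1.0000	0.2600	0.2821	0.8734	0.3886	0.8833	0.6323	0.2351	0.3704	0.2601	0.3420	0.4809	0.3522	0.7260	0.6862	0.6413
G	0.7236	0.2877	0.5157	0.3105	0.5251	1.0000	0.7158	0.2779	0.6575	0.2533	0.3704	0.6150	0.7223	0.6856	0.5220	0.7629	0.7019	0.5537	0.4880	0.4355
H	0.4514	0.3221	0.5233	0.6691	0.4506	0.6616	1.0000	0.2134	0.6627	0.4067	0.2251	0.7262	0.4995	0.9421	0.8823	0.6006	0.6639	0.2569	0.3380	0.4030
I	0.5513	0.9454	0.3402	0.2879	0.8455	0.4132	0.3622	1.0000	0.3302	0.7395	0.6558	0.3418	0.4021	0.3371	0.4276	0.4499	0.5518	0.6334	0.7301	0.7161
K	0.4635	0.3254	0.5260	0.6551	0.3261	0.4477	0.6307	0.2867	1.0000	0.3241	0.3504	0.9011	0.5365	0.6833	0.7362	0.4320	0.5005	0.3845	0.3067	0.2682
L	0.4669	0.7624	0.2440	0.2966	0.7799	0.2424	0.2663	0.9348	0.3972	1.0000	0.7695	0.2701	0.4869	0.1746	0.1711	0.4907	0.4272	0.7495	0.8888	0.7896
M	0.4952	0.7372	0.3419	0.2629	0.6192	0.4348	0.3307	0.7002	0.2442	0.6250	1.0000	0.1779	0.4185	0.3058	0.2095	0.5041	0.4630	0.7921	0.6514	0.6462
N	0.4778	0.3330	0.7533	0.8341	0.1255	0.4583	0.6299	0.2238	0.8242	0.2832	0.2104	1.0000	0.3080	0.8070	0.7092	0.6247	0.4891	0.2826	0.3132	0.2592
P	0.9284	0.3581	0.3602	0.3645	0.5054	0.7770	0.5786	0.4844	0.4812	0.5930	0.6151	0.4372	1.0000	0.6399	0.3826	0.6188	0.8079	0.4527	0.4994	0.4298
Q	0.4660	0.2101	0.5777	0.5062	0.3351	0.6905	0.8333	0.4006	0.8071	0.4310	0.4694	0.7751	0.6397	1.0000	0.8769	0.6214	0.4166	0.3704	0.3610	0.2614
R	0.3887	0.3683	0.4035	0.6704	0.2782	0.7054	0.8161	0.1899	0.7570	0.3622	0.4087	0.7526	0.5395	0.7386	1.0000	0.5031	0.6022	0.4500	0.3856	0.3760
S	0.5656	0.3666	0.3499	0.3883	0.3947	0.8155	0.5277	0.4203	0.4005	0.3017	0.2958	0.5580	0.6374	0.5654	0.5740	1.0000	0.6663	0.3305	0.5384	0.4737
T	0.7661	0.5089	0.3127	0.4023	0.4258	0.8161	0.5219	0.3510	0.3388	0.3378	0.6036	0.5530	0.7859	0.5512	0.4289	0.6470	1.0000	0.3394	0.4717	0.3938
V	0.6016	0.6611	0.1217	0.3698	0.8095	0.3337	0.4604	0.8431	0.1822	0.7899	0.8195	0.4103	0.5161	0.2911	0.2724	0.4743	0.5773	1.0000	0.8600	0.7536
W	0.4273	0.9446	0.0993	0.3439	0.7540	0.4007	0.4036	0.8268	0.2939	0.7402	0.7024	0.1659	0.5297	0.4179	0.2025	0.2679	0.3717	0.6669	1.0000	0.8341
Y	0.4751	0.7428	0.1419	0.2610	0.5983	0.3553	0.4929	0.6932	0.3194	0.5333	0.6509	0.3222	0.6996	0.4742	0.4135	0.5369	0.6568	0.6915	0.7595	1.0000
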