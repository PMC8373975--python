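S0000	S0001	S0002	S0003	S0004	S0005	S0006	S0007	S0008	S0009	S0010	S0011	S0012	S0013	S0014	S0015
G00000	12.428079	13.121291	12.80704	12.83214	12.853091	13.27215	12.856987	11.976404	12.961455	13.373224	12.072661	12.275279	12.795304	12.716791	13.694402	12.741154
G00001	11.098801	11.928679	11.526379	11.387549	11.401654	11.686258	11.757911	11.144026	10.819525	12.103151	10.719046	11.283644	11.426047	11.414169	11.902421	11.039113
G00002	13.316925	14.020699	14.172263	13.627809	14.000452	13.399416	13.608597	14.220112	13.481389	13.988945	14.114766	14.001397	13.019838	13.534462	14.353819	13.71739
G00003	14.885735	15.843954	15.244387	14.929529	15.073206	14.607944	15.287563	14.337402	14.722619	15.699982	14.795102	14.918325	14.650828	15.580579	15.180638	15.083144
G00004	15.843267	15.66418	16.238829	16.492814	15.994669	15.154524	16.129969	14.675447	15.674022	16.204869	15.755872	15.340705	15.699947	15.106132	16.089732	14.826715
G00005	13.733816	13.613564	13.873611	14.325122	14.356343	13.906291	14.061262	13.983511	13.367815	14.321398	13.849855	13.748087	13.804808	13.839731	14.020409	14.125748
G00006	17.897602	16.330057	15.924655	16.228621	16.614354	18.263463	16.613542	18.164491	17.975551	16.325408	17.347284	17.920094	17.834051	16.695687	16.483531	17.547438
G00007	12.27448	12.352461	11.710558	11.761977	11.647978	11.852439	12.290739	11.871331	11.544504	12.280755	11.843587	11.344866	12.129555	12.356413	11.751794	11.942349
G00008	8.690513	11.501732	11.957317	11.133542	11.568182	9.863985	11.560008	9.261053	9.675465	12.317307	9.691728	10.141021	9.856578	11.486907	12.356784	9.961355
G00009	10.198523	10.320117	10.709772	11.085794	10.159823	10.662665	10.674692	10.022544	10.653258	11.239354	10.20358	10.366872	10.06879	10.628069	10.572271	10.145577
G00010	10.602447	11.038349	11.43186	11.175298	11.744744	10.396602	11.803412	11.239773	11.27002	11.936703	10.652298	10.634451	11.142885	10.904621	11.83384	11.090187
G00011	12.331726	12.800066	11.6892	12.233976	12.443118	12.021641	12.439633	12.026825	12.106742	12.668509	11.7302	11.761613	12.04616	12.473471	12.338026	12.220513
G00012	13.325112	13.094605	12.776543	13.444446	13.487716	12.795075	13.273635	12.251468	12.203974	13.374579	12.245583	12.855691	13.506458	13.008879	13.91558	12.957249
G00013	8.407983	10.710309	9.803243	11.18643	11.168263	8.520361	10.984291	9.077254	9.346569	12.056658	8.648558	9.352505	8.613119	11.48237	11.283956	8.873376
G00014	14.010273	14.650699	13.784483	13.97244	14.414982	13.503591	13.407151	13.332107	13.789338	14.556691	13.167658	13.727108	13.668124	14.337631	14.299783	13.49634
G00015	12.996847	13.143122	13.009291	13.279815	12.772347	12.961451	12.630311	12.973565	13.339502	13.386746	13.39526	13.012579	12.306312	12.565982	13.394978	12.433646
G00016	12.712795	12.460677	12.356254	13.021306	11.997597	11.480057	12.749565	12.715309	12.654586	13.117583	12.687003	11.744631	12.112676	12.810434	12.929413	12.604981
G00017	12.218011	12.244767	13.016042	11.731165	12.008397	11.766321	11.991553	11.192174	11.724425	12.6078	11.842265	11.786882	11.868256	12.196728	12.417565	11.898196
G00018	16.648654	16.473648	16.763915	16.525737	16.154683	16.172083	16.639369	15.376895	16.212994	16.132301	17.361714	15.987779	16.060809	17.204548	16.715479	16.655812
G00019	13.324662	13.493725	13.435984	14.136207	13.94337	13.220799	13.716201	12.464593	12.885806	14.068782	13.346123	13.690066	13.396492	14.026888	14.085351	13.254297
G00020	11.343414	12.10895	12.252893	11.843647	12.358798	11.420604	12.154158	11.704378	11.94106	12.559686	11.544274	11.338958	11.700881	11.860622	12.368021	12.523248
G00021	11.476151	12.409678	12.128072	11.701266	12.049827	11.874776	12.253119	11.649373	12.007604	12.312925	11.863426	11.557364	11.421874	12.392816	12.441053	11.808072
G00022	15.125764	16.005505	15.880451	15.898675	16.020506	15.471381	15.899777	16.225884	15.67796	16.004714	15.333403	15.680709	15.549778	15.919798	16.144652	16.128111
G00023	11.714371	12.646395	12.645355	12.263884	12.077253	12.125272	12.279884	12.327369	11.991484	12.393275	12.353782	12.169595	12.308775	12.195501	12.876506	12.369448
G00024	14.756299	14.53618	14.761329	15.276731	15.308148	14.664426	14.570623	14.895389	14.331018	15.580966	14.900867	14.770001	14.88131	15.231037	14.773779	14.77188
G00025	14.169597	14.889883	15.303749	15.398399	15.230466	14.385438	14.819785	14.822138	14.485772	15.126048	14.442134	14.507073	14.749958	14.923987	15.303232	14.677587
G00026	6.914116	9.774935	9.321563	9.438461	9.874717	7.488771	9.580245	7.225607	8.079107	10.413886	7.585648	7.970304	7.931926	10.02479	10.34553	8.142433
G00027	15.171675	15.818918	14.931662	14.980102	15.402977	15.234359	15.600024	14.981074	15.070915	15.543861	15.197581	14.900259	15.20191	15.723281	15.581454	15.259464
G00028	12.347534	12.931295	12.876554	12.580255	12.904441	13.105402	13.114272	12.885956	12.511489	13.2478	12.840374	12.594944	12.740069	13.092158	12.900365	12.92612
G00029	13.144111	11.663731	11.7055	11.966867	12.08949	13.019705	11.318001	12.91775	12.865852	11.807948	12.654769	12.898666	12.399018	11.528157	11.428424	12.669818
G00030	11.205759	12.003334	11.087989	11.924263	11.944757	11.487167	11.601614	11.654178	10.968768	12.54415	11.218723	11.646903	10.97316	11.453442	11.293671	10.882107
G00031	13.988894	14.409025	14.157102	14.487048	14.809315	14.123578	14.422144	13.42648	13.981524	14.732915	14.186664	14.258761	14.178874	14.313836	14.618586	14.497395
G00032	12.783425	14.213408	14.048174	13.643972	13.401704	12.646449	13.482102	13.53609	13.521726	13.84777	13.174033	12.84506	13.243414	13.690475	13.922041	13.529122
G00033	13.307723	12.997215	13.227841	13.370726	12.868368	12.922874	13.420973	13.053885	12.530074	12.956501	12.867768	12.862211	12.995159	12.971755	13.428297	12.85021
G00034	11.768159	12.586121	12.396008	11.469522	12.385004	12.073912	11.864685	12.331743	12.108382	12.134438	12.195018	11.833123	11.642414	12.48495	12.514344	12.171764
G00035	16.718451	15.003387	14.739671	15.022168	15.512861	16.339799	15.3534	16.258741	16.135552	15.370837	16.133109	16.027309	16.26879	14.548695	14.576287	16.44498
G00036	14.816501	16.080974	16.024141	15.702047	15.83693	15.236082	15.728605	15.296324	15.458627	15.720362	15.001876	16.067249	15.727183	15.69095	16.1241	15.227394
G00037	15.522352	16.180716	16.307596	15.802013	15.637238	15.432411	15.665648	15.827067	15.358751	15.952517	15.619425	15.508028	15.94217	15.712529	16.273025	15.837081
G00038	14.769622	14.965849	15.170541	14.706709	15.254306	14.237191	14.642201	14.855619	14.619318	15.613492	14.732978	14.961876	14.830306	15.059295	15.239774	14.405214
G00039	15.732751	15.655779	15.949502	15.922551	15.841698	16.182107	16.43405	16.135371	16.046451	16.389743	15.581026	15.827978	15.808546	16.333315	15.817515	15.694828
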