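exposure	method	nsnp	beta	se	p	pleiotropy_p	heterogeneity_p
Glucuronate levels	IVW	15	-0.001073114	0.000493748	0.029749906	0.672252265	0.508686618
Ribitol levels	IVW	31	-0.000564724	0.000276122	0.040835359	0.322705789	0.510022801
Indolelactate levels	IVW	26	0.000863361	0.000351756	0.014110884	0.896340896	0.492778623
1-Oleoylglycerol (18:1) levels	IVW	30	-0.000920088	0.000326152	0.004786855	0.708129301	0.99698244
Docosatrienoate (22:3n3) levels	IVW	21	-0.000810321	0.000373952	0.030241769	0.962491013	0.123548475
3-Hydroxy-2-ethylpropionate levels	IVW	27	-0.000979664	0.000355352	0.005835483	0.896340896	0.351617201
Stachydrine levels	IVW	22	-0.001232526	0.00039843	0.001978389	0.2604085	0.685471992
Stearoylcarnitine levels	IVW	20	-0.000848802	0.000352243	0.015965453	0.562548286	0.562160925
5-Acetylamino-6-amino-3-methyluracil levels	IVW	33	-0.000512983	0.00025364	0.0431262	0.67044135	0.493700068
Malonylcarnitine levels	IVW	20	0.000771063	0.000365568	0.034925568	0.987882437	0.470040683
Tetradecanedioate (C14-DC) levels	IVW	18	0.000580039	0.000271679	0.032759906	0.756005857	0.619121414
4-Vinylphenol sulfate levels	IVW	24	0.000941283	0.000378089	0.012789434	0.542426062	0.840201128
2-Oxoarginine levels	IVW	21	-0.000830219	0.000396509	0.036275909	0.273105846	0.459863594
Eicosanedioate (C20-DC) levels	IVW	15	0.000860592	0.000437744	0.049302087	0.792420863	0.775798229
Imidazole propionate levels	IVW	24	0.000981042	0.000415176	0.018129807	0.721914496	0.142885881
17-alpha-hydroxypregnanolone glucuronide levels	IVW	30	0.000640777	0.000261465	0.014257319	0.42036626	0.850243988
Behenoyl sphingomyelin (d18:1/22:0) levels	IVW	18	-0.001323989	0.000454063	0.00354697	0.773036829	0.672919237
N-carbamoylalanine levels	IVW	21	0.000821954	0.000404294	0.042046619	0.163320963	0.495662387
Furaneol sulfate levels	IVW	11	-0.001194722	0.000387159	0.002029593	0.758521985	0.387838131
Pimeloylcarnitine/3-methyladipoylcarnitine (C7-DC) levels	IVW	26	0.000644744	0.000307827	0.036215529	0.573274801	0.63601432
Hexadecenedioate (C16:1-DC) levels	IVW	30	0.000535537	0.000235754	0.023111081	0.950517512	0.159826409
6-Bromotryptophan levels	IVW	21	0.000564317	0.000264941	0.033173746	0.802329031	0.617427275
Vanillylmandelate (VMA) levels	IVW	36	0.000651841	0.000330953	0.048885335	0.852803281	0.328929123
Choline levels	IVW	23	0.000837533	0.000387371	0.030610621	0.577209394	0.829305676
Cholesterol levels	IVW	19	-0.001030859	0.000435026	0.01780495	0.659744227	0.902878224
Palmitate (16:0) levels	IVW	21	-0.000940653	0.000412139	0.022467497	0.430423177	0.749625121
Alanine levels	IVW	22	-0.00102685	0.000397194	0.009730642	0.58687087	0.316597781
Dihydroorotate levels	IVW	27	-0.00069695	0.000268615	0.009469867	0.453403803	0.535758665
X-12410 levels	IVW	25	-0.000629179	0.000308666	0.041511874	0.427454548	0.780602082
X-12730 levels	IVW	17	-0.000917951	0.000414738	0.02687506	0.342444621	0.494976624
X-12847 levels	IVW	18	-0.000916559	0.00040313	0.022989764	0.914878806	0.971327996
X-21845 levels	IVW	19	0.000740044	0.000334858	0.027103601	0.447927278	0.572496689
X-24334 levels	IVW	19	0.000835775	0.000375051	0.025851911	0.102874872	0.801032771
X-24951 levels	IVW	20	-0.000960857	0.000439041	0.028630347	0.585691878	0.588387057
Carnitine C4 levels	IVW	35	0.000389928	0.000168303	0.020513431	0.123832776	0.387945445
Deoxycholic acid glucuronide levels	IVW	27	0.000458834	0.000176529	0.009344124	0.479610339	0.879728137
Uridine to pseudouridine ratio	IVW	23	-0.00100743	0.000383588	0.008631073	0.802356942	0.812061777
Carnitine to palmitoylcarnitine (C16) ratio	IVW	27	0.000763943	0.000366825	0.037289566	0.098773213	0.230796097
Spermidine to N-acetylputrescine ratio	IVW	18	0.000805473	0.000313881	0.010282831	0.262554894	0.500339034
Spermidine to taurocholate ratio	IVW	15	-0.001013176	0.000438562	0.02087584	0.992689842	0.425962635
Adenosine 5'-diphosphate (ADP) to oxalate (ethanedioate) ratio	IVW	20	-0.00043365	0.00019485	0.026043769	0.674464959	0.275077181
Phosphate to threonine ratio	IVW	28	0.000687417	0.000343907	0.045624904	0.653124394	0.630672608
Adenosine 5'-monophosphate (AMP) to aspartate ratio	IVW	27	-0.000895149	0.000398034	0.024517199	0.646932116	0.203770025
Adenosine 5'-monophosphate (AMP) to asparagine ratio	IVW	23	0.000882091	0.000362747	0.015028189	0.221894762	0.546281333
Adenosine 5'-monophosphate (AMP) to histidine ratio	IVW	22	0.00084553	0.000403867	0.036297128	0.161108246	0.813517111
Phosphate to asparagine ratio	IVW	25	0.000517017	0.000260738	0.04737847	0.469564479	0.461583735
Fructose to sucrose ratio	IVW	23	-0.000840704	0.000423094	0.046917858	0.683740135	0.218612378
Proline to glutamate ratio	IVW	23	0.000767642	0.000371864	0.038988355	0.672364772	0.50566083
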