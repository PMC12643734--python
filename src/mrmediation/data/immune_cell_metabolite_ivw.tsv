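exposure	outcome	method	nsnp	beta	se	p	pleiotropy_p	heterogeneity_p
CD62L- monocyte AC	4-Vinylphenol sulfate levels	IVW	19	0.052975	0.021327	0.012996	0.54723	0.156234
CD62L- monocyte AC	N-carbamoylalanine levels	IVW	19	0.038573	0.019375	0.04649	0.675362	0.94402
CM CD4+ AC	Furaneol sulfate levels	IVW	27	0.047458	0.021097	0.024479	0.33262	0.731649
CM CD4+ AC	X-12730 levels	IVW	27	-0.05298	0.020882	0.011181	0.162045	0.241126
CD4/CD8br	Ribitol levels	IVW	14	0.063061	0.028827	0.028699	0.411288	0.740109
CD4/CD8br	5-Acetylamino-6-amino-3-methyluracil levels	IVW	15	0.074318	0.028212	0.008432	0.728498	0.602304
CD4/CD8br	Choline levels	IVW	14	0.093112	0.028287	0.000996	0.112575	0.39616
CD4/CD8br	Alanine levels	IVW	14	0.074704	0.028811	0.009518	0.925977	0.947555
CD4/CD8br	Proline to glutamate ratio	IVW	15	-0.07821	0.029361	0.007724	0.537947	0.280965
CD8br %T cell	N-carbamoylalanine levels	IVW	22	-0.06001	0.021912	0.006165	0.373647	0.404012
CD8br %T cell	Choline levels	IVW	22	-0.05082	0.01972	0.00997	0.076184	0.678741
CD8br %T cell	Cholesterol levels	IVW	22	0.044784	0.02008	0.025733	0.689419	0.902292
CD8br %T cell	Proline to glutamate ratio	IVW	22	0.05163	0.02204	0.019149	0.753992	0.248405
HLA DR+ CD4+ AC	Deoxycholic acid glucuronide levels	IVW	23	0.041456	0.018894	0.028222	0.696276	0.168556
HLA DR+ CD4+ AC	Phosphate to threonine ratio	IVW	23	-0.04212	0.01856	0.023237	0.949595	0.18766
CD19 on IgD- CD24-	4-Vinylphenol sulfate levels	IVW	23	-0.06027	0.024512	0.013938	0.393824	0.332163
CD19 on IgD- CD24-	Deoxycholic acid glucuronide levels	IVW	23	0.063011	0.023134	0.006454	0.960251	0.937835
CD19 on IgD- CD27-	Ribitol levels	IVW	25	0.059288	0.027523	0.031228	0.273614	0.212937
CD19 on IgD- CD27-	Vanillylmandelate (VMA) levels	IVW	25	0.051717	0.022296	0.020364	0.67025	0.406206
CD38 on IgD+ CD24-	Pimeloylcarnitine/3-methyladipoylcarnitine (C7-DC) levels	IVW	17	0.051875	0.024811	0.036545	0.789512	0.797948
CD38 on IgD+ CD24-	6-Bromotryptophan levels	IVW	17	-0.06053	0.027981	0.030521	0.210795	0.210313
CD28 on CD28+ CD4+	Fructose to sucrose ratio	IVW	26	-0.04119	0.018341	0.024727	0.335881	0.122878
CD28 on CD28+ CD4+	Proline to glutamate ratio	IVW	26	-0.0309	0.01512	0.040986	0.917296	0.719477
CD28 on CD39+ resting Treg	X-24951 levels	IVW	21	0.025977	0.010146	0.010462	0.187173	0.340688
CD28 on CD39+ resting Treg	Adenosine 5'-diphosphate (ADP) to oxalate (ethanedioate) ratio	IVW	21	-0.03186	0.013204	0.015835	0.945799	0.772005
SSC-A on plasmacytoid DC	2-Hydroxysebacate levels	IVW	25	0.042265	0.017585	0.016243	0.586718	0.498197
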