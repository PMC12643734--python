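exposure	method	nsnp	beta	se	p	pleiotropy_p	heterogeneity_p	reverse_p
CD62L- monocyte AC	IVW	17	-0.000705457	0.000232857	0.002449007	0.904514294	0.45108964	0.264197877
CD62L- HLA DR++ monocyte AC	IVW	18	-0.000663598	0.000263556	0.011806743	0.64212189	0.54134284	0.449976501
CD33br HLA DR+ CD14- %CD33br HLA DR+	IVW	18	0.000324511	0.000140503	0.020908324	0.089434862	0.592847871	0.77823041
CM CD4+ AC	IVW	27	0.000438861	0.000159215	0.005843978	0.07376658	0.831651648	0.212331087
CD4/CD8br	IVW	14	0.000887721	0.000248336	0.00035067	0.239541989	0.796021902	0.989409668
CD8br %T cell	IVW	19	-0.000448204	0.000209451	0.032363103	0.084345437	0.244448036	0.723923349
HLA DR+ T cell %T cell	IVW	32	-0.000247053	0.000113832	0.029981463	0.138489033	0.361865651	0.716265763
HLA DR+ CD4+ AC	IVW	23	-0.000487661	0.000216299	0.024160599	0.276157626	0.070483553	0.291022594
CD19 on IgD- CD24-	IVW	21	-0.000520096	0.000229416	0.023387427	0.261092829	0.217340761	0.374596636
CD19 on IgD- CD27-	IVW	25	-0.000508478	0.000230027	0.027069552	0.212012777	0.126478444	0.437236491
CD38 on IgD+ CD24-	IVW	15	0.000496815	0.00022601	0.027935194	0.310776526	0.493769101	0.687729526
CD28 on CD28+ CD4+	IVW	28	-0.00029823	0.000129736	0.021519618	0.702878681	0.784913233	0.051456115
CD28 on CD39+ resting Treg	IVW	19	-0.000250477	0.000103235	0.015253905	0.393224747	0.237972715	0.657141481
SSC-A on plasmacytoid DC	IVW	25	-0.00037218	0.000150992	0.013705485	0.306308088	0.822970804	0.238302703
CD11b on CD33br HLA DR+ CD14dim	IVW	21	-0.00030241	0.000143023	0.034479349	0.629497968	0.868123394	0.646727819
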