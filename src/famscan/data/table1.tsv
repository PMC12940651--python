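name	gene_id	chromosome	exon_count	strand	length_aa	pI	mw_da	group	ortholog	ortholog_evalue	subgroup	corrected	partial
TgMADS01	Tg01g02120.t1	1	8	-	245	7.793	27777.64	MIKC	AGL18	3e-49	AGL15	0	0
TgMADS02	Tg01g02320.t1	1	8	-	245	7.793	27777.64	MIKC	AGL18	3e-49	AGL15	0	0
TgMADS03	Tg02g16980.t1	2	7	+	180	9.556	20710.30	MIKC	AG	5e-89	AG (C/D)	0	0
TgMADS04	Tg02g17630.t1	2	1	+	217	6.083	24501.89	M-type	AGL62	3e-27	α	1	0
TgMADS05	Tg02g17650.t1	2	1	+	217	6.083	24501.89	M-type	AGL62	3e-27	α	1	0
TgMADS06	Tg03g08370.t1	3	4	+	266	7.841	31046.34	MIKC	ABS	2e-44	Bsis	0	0
TgMADS07	Tg03g12830.t1	3	1	-	182	9.241	20526.35	M-type	AGL80	1e-20	γ	0	0
TgMADS08	Tg03g12970.t1	3	6	-	212	9.548	24662.10	MIKC	STK	4e-96	AG (C/D)	0	0
TgMADS09	Tg03g13060.t1	3	7	+	215	8.2	24680.66	MIKC	AGL12	9e-62	AGL12	0	0
TgMADS10	Tg03g18430.t1	3	5	-	232	7.72	26277.56	MIKC	AGL104	8e-32	MIKC*	0	0
TgMADS11	Tg03g18920.t1	3	5	+	225	6.654	25350.35	MIKC	AGL66	2e-32	MIKC*	0	0
TgMADS12	Tg04g01300.t1	4	1	-	441	6.118	50996.38	M-type	AGL47	1e-18	γ	0	0
TgMADS13	Tg05g03610.t1	5	6	-	203	6.329	23680.87	MIKC	PI	8e-80	DEF/GLO (B)	0	0
TgMADS14	Tg05g04300.t1	5	1	-	512	5.19	54680.51	M-type	AGL62	4e-26	α	0	0
TgMADS15	Tg05g05250.t1	5	1	+	512	5.133	54695.52	M-type	AGL62	3e-26	α	0	0
TgMADS16	Tg05g13890.t1	5	7	+	242	7.263	27155.79	MIKC	AGL15	5e-48	AGL15	0	0
TgMADS17	Tg05g16950.t1	5	5	+	189	8.515	21175.17	MIKC	AGL6	4e-65	AGL6	0	0
TgMADS18	Tg05g17300.t1	5	5	+	189	8.515	21175.17	MIKC	AGL6	4e-65	AGL6	0	0
TgMADS19	Tg06g03090.t1	6	5	-	178	5.736	19809.03	MIKC	AGL6	9e-41	AGL6	0	0
TgMADS20	Tg06g03840.t1	6	1	-	262	9.082	30062.66	M-type	AGL35	1e-19	γ	0	0
TgMADS21	Tg06g05880.t1	6	1	-	257	8.127	28493.16	M-type	AGL80	7e-49	γ	0	0
TgMADS22	Tg06g08110.t1	6	7	-	288	6.323	32718.19	MIKC	AGL15	6e-35	AGL15	1	0
TgMADS23	Tg06g09940.t1	6	1	-	280	9.367	30791.43	M-type	AGL61	5e-37	α	0	0
TgMADS24	Tg06g11190.t1	6	1	-	255	8.754	27856.53	M-type	AGL80	2e-59	γ	0	0
TgMADS25	Tg12gnew.t1	12	7	+	228	9.272	26076.47	MIKC	AGL21	3e-86	AGL17 (ANR1)	1	0
TgMADS26	Tg07g06420.t1	7	5	+	184	9.059	20794.48	MIKC	FUL	3e-51	SQUA (A)	0	0
TgMADS27	Tg07g08930.t1	7	6	-	198	9.106	22548.31	MIKC	AGL21	4e-65	AGL17 (ANR1)	1	0
TgMADS28	Tg07g13640.t1	7	8	-	227	5.779	25708.82	MIKC	SVP	1e-106	STMADS11 (SVP)	0	0
TgMADS29	Tg07g14620.t1	7	8	+	326	6.098	37662.41	MIKC	AGL67	5e-19	MIKC*	1	0
TgMADS30	Tg08g10570.t1	8	6	-	222	8.635	25471.88	MIKC	AGL16	1e-90	AGL17 (ANR1)	0	0
TgMADS31	Tg08g12890.t1	8	1	+	305	8.086	34967.83	M-type	AGL47	5e-24	γ	0	0
TgMADS32	Tg08g12940.t1	8	1	+	269	6.176	30947.26	M-type	AGL47	1e-25	γ	0	0
TgMADS33	Tg08g14560.t1	8	1	-	249	5.23	27010.24	M-type	AGL62	3e-29	α	0	0
TgMADS34	Tg08g14570.t1	8	1	-	248	7.467	28084.16	M-type	AGL62	3e-50	α	0	0
TgMADS35	Tg09g00890.t1	9	6	+	218	7.807	24813.87	MIKC	SEP2	1e-101	SEP (E)	0	0
TgMADS36	Tg09g00900.t1	9	6	+	220	9.438	25887.28	MIKC	FUL	1e-60	SQUA (A)	1	0
TgMADS37	Tg09g02970.t1	9	1	-	335	8.377	38451.84	M-type	AGL82	4e-20	γ	0	0
TgMADS38	Tg09g10160.t1	9	8	-	228	6.521	25795.07	MIKC	SVP	1e-113	STMADS11 (SVP)	0	0
TgMADS39	Tg09g12140.t1	9	3	-	172	6.055	19369.54	MIKC	AP3	2e-21	DEF/GLO (B)	1	0
TgMADS40	Tg10g05610.t1	10	6	+	320	5.816	36419.86	MIKC	AGL65	5e-44	MIKC*	0	0
TgMADS41	Tg10g06570.t1	10	5	+	181	8.109	20447.95	MIKC	FUL	6e-45	SQUA (A)	0	0
TgMADS42	Tg11g05170.t1	11	5	+	185	8.103	21076.69	MIKC	FUL	2e-51	SQUA (A)	0	0
TgMADS43	Tg11g11530.t1	11	8	-	259	7.997	29823.83	MIKC	AP1	1e-105	SQUA (A)	0	0
TgMADS44	Tg11g11540.t1	11	8	-	238	8.408	27297.68	MIKC	SEP4	8e-89	SEP (E)	0	0
TgMADS45	Tg11g14500.t1	11	7	-	187	8.599	21300.46	MIKC	MAF3	8e-38	FLC	1	0
TgMADS46	Tg11g14510.t1	11	6	-	214	8.399	24197.23	MIKC	SEP3	1e-111	SEP (E)	0	0
TgMADS47	Tg12g09890.t1	12	6	+	206	8.455	23037.09	MIKC	AGL24	5e-58	STMADS11 (SVP)	1	0
TgMADS48	Tg12g10450.t1	12	14	-	400	8.94	45465.40	MIKC	ANR1	5e-42	AGL17 (ANR1)	1	0
TgMADS49	Tg12g10710.t1	12	12	+	342	9.122	39025.15	MIKC	ANR1	1e-42	AGL17 (ANR1)	1	0
TgMADS50	Tg12g10730.t1	12	7	+	234	8.587	26692.53	MIKC	AGL21	1e-87	AGL17 (ANR1)	0	0
TgMADS51	Tg12g10740.t1	12	7	+	246	7.537	27560.23	MIKC	AGL16	1e-72	AGL17 (ANR1)	1	0
TgMADS52	Tg12g11440.t1	12	1	-	332	5.971	36820.75	M-type	AGL62	2e-38	α	0	0
TgMADS53	Tg12g11450.t1	12	1	-	338	5.775	36382.70	M-type	AGL62	7e-41	α	0	0
TgMADS54	Tg12g11460.t1	12	1	-	218	8.785	24618.95	M-type	AGL23	4e-35	α	0	0
TgMADS55	Tg12g11470.t1	12	1	-	236	8.327	25952.45	M-type	AGL40	2e-35	α	0	0
TgMADS56	Tg12g11480.t1	12	1	-	286	8.281	31056.86	M-type	AGL28	1e-29	α	0	0
TgMADS57	Tg13g04470.t1	13	7	+	272	9.361	31573.91	MIKC	SHP1	1e-111	AG (C/D)	0	0
TgMADS58	Tg13g08100.t1	13	1	+	157	9.188	18603.25	M-type	AGL45	7e-17	γ	0	0
TgMADS59	Tg13g08220.t1	13	1	-	188	8.956	21716.79	M-type	AGL45	4e-20	γ	0	0
TgMADS60	Tg14g04500.t1	14	1	+	180	8.876	20944.87	M-type	AGL29	3e-30	α	0	0
TgMADS61	Tg15g03960.t1	15	7	-	217	7.666	24841.28	MIKC	MAF2	6e-33	FLC	1	0
TgMADS62	Tg15g08040.t1	15	6	+	214	8.57	24725.49	MIKC	FYF	4e-64	SOC1/TM3	1	0
TgMADS63	Tg15g12120.t1	15	6	+	213	7.963	24092.98	MIKC	SEP4	4e-60	SEP (E)	0	0
TgMADS64	Tg15g12130.t1	15	5	+	187	6.481	21347.13	MIKC	AP1	1e-60	SQUA (A)	0	0
TgMADS65	Tg16g04330.t1	16	1	-	169	5.426	18449.26	M-type	AGL61	1e-16	α	0	0
TgMADS66	Tg16g06210.t1	16	8	+	208	8.539	24148.02	MIKC	AGL19	3e-55	SOC1/TM3	1	0
TgMADS67	Tg16g08830.t1	16	8	+	202	9.321	23463.77	MIKC	TM8	9e-93	TM8	0	0
TgMADS68	Tg16g13620.t1	16	1	+	341	8.465	39207.77	M-type	AGL47	8e-23	γ	0	0
TgMADS69	Tg17g01590.t1	17	9	-	244	8.824	28212.51	MIKC	AG	1e-101	AG (C/D)	0	0
TgMADS70	Tg17g11550.t1	17	5	+	196	8.399	22728.76	MIKC	AG	4e-69	AG (C/D)	0	0
TgMADS71	Tg17g14050.t1	17	6	-	204	5.185	22642.22	MIKC	AGL104	1e-29	MIKC*	1	0
TgMADS72	Tg18g00180.t1	18	6	+	274	8.956	31067.39	MIKC	STK	2e-87	AG (C/D)	0	0
TgMADS73	Tg18g03780.t1	18	5	-	181	9.068	21234.95	MIKC	AP3	7e-55	DEF/GLO (B)	0	0
TgMADS74	Tg18g12570.t1	18	1	-	180	5.239	19540.09	M-type	AGL62	6e-18	α	0	0
TgMADS75	TgUn065g00050.t1	Un65	1	-	180	5.239	19584.10	M-type	AGL62	2e-17	α	0	0
TgMADS76	TgUn001g00120.t1	Un001	7	+	214	8.71	24498.73	MIKC	AGL19	2e-71	SOC1/TM3	0	0
TgMADS77	TgUn001g00290.t1	Un001	7	-	214	8.71	24498.73	MIKC	AGL19	2e-71	SOC1/TM3	0	0
TgMADS78	TgUn357g00010.t1	Un357	5	-	181	8.109	20447.95	MIKC	FUL	6e-45	SQUA (A)	0	0
TgMADS79	TgUn447g00010.t1	Un447	2	-	75	9.688	8350.45	MIKC	ANR1	2e-35	AGL17 (ANR1)	1	1
TgMADS80	TgUn530g00010.t1	Un530	1	+	306	8.864	33279.50	M-type	AGL62	5e-39	α	0	0
TgMADS81	TgUn530g00020.t1	Un530	1	+	236	8.327	25910.37	M-type	AGL62	3e-42	α	0	0
TgMADS82	TgUn530g00030.t1	Un530	1	+	218	8.785	24604.93	M-type	AGL23	6e-35	α	0	0
TgMADS83	TgUn530g00050.t1	Un530	2	+	300	7.422	34065.09	M-type	AGL62	3e-38	α	0	0
TgMADS84	TgUn613g00040.t1	Un613	8	-	285	8.241	32590.56	MIKC	AG	1e-103	AG (C/D)	1	0
TgMADS85	TgUn699g00040.t1	Un699	1	+	332	5.971	36824.74	M-type	AGL62	2e-38	α	0	0
TgMADS86	TgUn699g00020.t1	Un699	1	+	191	8.978	21292.71	M-type	AGL62	3e-40	α	0	0
TgMADS87	TgUn766g00020.t1	Un766	2	-	237	8.579	27249.67	MIKC	FUL	6e-68	SQUA (A)	0	0
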