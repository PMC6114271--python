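compound_id	herb_codes	chemical_name	ob	dl	degree
C01	CR01	ZINC03982454	36.91	0.76	2
C02	CR02	Cycloartenol	38.69	0.78	1
C03	CR03,MO13,AS01,PC14	Beta-sitosterol	36.91	0.75	38
C04	CR04	3,2′,4′,6′-Tetrahydroxy-4,3′-dimethoxy chalcone	52.69	0.28	11
C05	CR05	Curculigoside B_qt	83.36	0.19	5
C06	CR06,AS02,AR07,PC10	Stigmasterol	43.83	0.76	31
C07	EH01	24-Epicampesterol	37.58	0.71	2
C08	EH02	Linoleyl acetate	42.1	0.2	4
C09	EH03,PC22	Poriferast-5-en-3beta-ol	36.91	0.75	2
C10	EH04	DFV	32.76	0.18	11
C11	EH05	Chryseriol	35.85	0.27	18
C12	EH06,MO12	Sitosterol	36.91	0.75	3
C13	EH07,AR02	Kaempferol	41.88	0.24	63
C14	EH08	Olivil	62.23	0.41	4
C15	EH09,AR03	Anhydroicaritin	45.41	0.44	37
C16	EH10	C-Homoerythrinan,1,6-didehydro-3,15,16-trimethoxy-,(3.beta.)-	39.14	0.49	38
C17	EH11	Yinyanghuo A	56.96	0.77	9
C18	EH12	Yinyanghuo C	45.67	0.51	1
C19	EH13	Yinyanghuo E	51.63	0.55	11
C20	EH14	6-Hydroxy-11,12-dimethoxy-2,2-dimethyl-1,8-dioxo-2,3,4,8-tetrahydro-1H-isochromeno[3,4-h]isoquinolin-2-ium	60.64	0.66	6
C21	EH15	8-(3-Methylbut-2-enyl)-2-phenyl-chromone	48.54	0.25	30
C22	EH16	Anhydroicaritin-3-O-alpha-L-rhamnoside	41.58	0.61	1
C23	EH17	1,2-bis(4-Hydroxy-3-methoxyphenyl)propan-1,3-diol	52.31	0.22	11
C24	EH18	Icariin	41.58	0.61	1
C25	EH19	Icariside A7	31.91	0.86	3
C26	EH20	Luteolin	36.16	0.25	57
C27	EH21,PC15	Magnograndiolide	63.71	0.19	4
C28	EH22,PC19	Quercetin	46.43	0.28	153
C29	MO01	Ethyl oleate (NF)	32.4	0.19	1
C30	MO02	Alizarin-2-methylether	32.81	0.21	13
C31	MO03	1-Hydroxy-6-hydroxymethylanthracenequinone	81.77	0.21	12
C32	MO04	(2R,3S)-(+)-3′,5-Dihydroxy-4,7-dimethoxydihydroflavonol	77.24	0.33	9
C33	MO05	1,6-Dihydroxy-5-methoxy-2-(methoxymethyl)-9,10-anthraquinone	104.54	0.34	12
C34	MO06	Americanin A	46.71	0.35	11
C35	MO07	2-Hydroxy-1,8-dimethoxy-7-methoxymethylanthracenequinone	112.3	0.37	11
C36	MO08	2-Hydroxy-1,5-dimethoxy-6-(methoxymethyl)-9,10-anthraquinone	95.85	0.37	14
C37	MO09	1,5,7-Trihydroxy-6-methoxy-2-methoxymethylanthracenequinone	80.42	0.38	10
C38	MO10	Diop	43.59	0.39	3
C39	MO11	3beta,20(R),5-alkenyl-stigmastol	36.91	0.75	1
C40	MO14	Isoprincepin	49.12	0.77	2
C41	MO15	3beta-24S(R)-butyl-5-alkenyl-cholestol	35.35	0.82	1
C42	MO16	Ohioensin-A	38.13	0.76	3
C43	AR01	Asperglaucide	58.02	0.52	5
C44	AR04	Anemarsaponin F_qt	60.06	0.79	1
C45	AR05	Hippeastrine	51.65	0.62	11
C46	AR06	Timosaponin B III_qt	35.26	0.87	2
C47	AR08	Icariin I	41.58	0.61	1
C48	AR09	(Z)-3-(4-hydroxy-3-methoxy-phenyl)-N-[2-(4-hydroxyphenyl)ethyl]acrylamide	118.35	0.26	8
C49	AR10	Diosgenin	80.88	0.81	16
C50	AR11	Coumaroyltyramine	112.9	0.2	10
C51	PC01	Berberine	36.86	0.78	17
C52	PC02	Coptisine	30.67	0.86	9
C53	PC03	Phellavin_qt	35.86	0.44	3
C54	PC04	Delta 7-stigmastenol	37.42	0.75	1
C55	PC05	Phellopterin	40.19	0.28	12
C56	PC06	Dehydrotanshinone II A	43.76	0.42	1
C57	PC07	Rutaecarpine	40.3	0.61	8
C58	PC08	Skimmianin	40.14	0.2	5
C59	PC09	Chelerythrine	34.18	0.78	6
C60	PC11	Worenine	45.83	0.87	7
C61	PC12	Cavidine	35.64	0.81	28
C62	PC13	Hericenone H	39	0.63	1
C63	PC16	Palmatine	64.6	0.65	19
C64	PC17	Fumarine	59.26	0.83	28
C65	PC18	Isocorypalmine	35.77	0.59	36
C66	PC20	Phellamurin_qt	56.6	0.39	10
C67	PC21	(S)-Canadine	53.83	0.77	32
C68	PC23	Berberrubine	35.74	0.73	13
C69	PC24	Campesterol	37.58	0.71	1
C70	PC25	Thalifendine	44.41	0.73	14
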