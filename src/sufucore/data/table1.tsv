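compound	chem_class	threshold	odor	d0	d10	d20	d30	d60	d90	d130
Ethyl propionate	ester	0.01	Pineapple	−	−	4.28	5.63	6.02	15.72	7.73
Ethyl butanoate	ester	0.001	Fruity, banana	28.2	22.26	27.43	20.13	21.01	16.64	16.49
Ethyl isobutyrate	ester	0.0001	Fruity	−	2.61	9.62	6.30	9.69	10.09	9.65
Ethyl 2-methyl butyrate	ester	0.00015	Grassy	5.71	20.52	54.25	33.60	18.06	30.45	26.65
Ethyl valerate	ester	0.0058	Fruity	27.30	29.30	36.53	36.05	44.40	27.75	42.49
Ethyl isovalerate	ester	0.0002	Nail polish	−	6.02	15.65	9.56	5.88	8.13	13.64
Emyl acetate	ester	0.05		6.32	5.69	7.00	11.41	11.8	8.17	6.39
Ethyl hexanoate	ester	0.005	Almond, apple	217.70	264.25	430.11	339.45	465.58	321.63	618.33
Ethyl oenanthate	ester	0.0019	Fruity	101.95	105.45	181.42	149.67	156.23	106.57	216.38
Ethyl caprylate	ester	0.0193	Creamy	−	160.78	252.49	230.12	326.10	249.80	329.22
4-decanolide	ester	0.0026	Fruity, peach	5.61	6.30	10.97	11.01	7.34	5.57	9.53
Ethyl caprate	ester	0.023	Flower	28.71	11.40	20.80	20.51	16.38	15.62	90.29
Ethyl benzoate	ester	0.053		−	−	−	4.52	4.79	4.38	6.64
Propyl(E)-2-methyl-2-Butenoate	ester	0.012		−	−	−	−	2.65	1.50	3.90
Isoamyl alcohol	alcohol	0.22	Alcoholic	80.14	82.81	93.62	116.33	39.16	40.74	44.30
Hexyl alcohol	alcohol	0.5	Sour, pungent	85.94	87.84	101.42	100.37	96.86	58.28	79.68
1-octene-3-ol	alcohol	0.007	Mushroom fragrance	−	106.57	224.22	178.42	201.00	207.58	182.19
2-octyne-1-ol	alcohol	0.003		24.59	20.32	24.86	57.40	31.40	20.55	13.09
(E)-2-octene-1-ol	alcohol	0.02		9.20	7.88	14.18	41.97	10.74	7.93	8.78
Eudesmol	alcohol	0.003	Herb	−	5.28	4.41	26.14	13.60	8.19	10.67
Linalool	alcohol	0.006	Lily	4.48	7.33	5.61	44.75	3.99	5.51	8.22
1-nonanol	alcohol	0.05		9.22	8.56	12.28	9.27	6.74	5.83	5.69
Pentanal	aldehyde	0.012	Pungent	14.59	13.75	18.23	13.02	19.69	14.56	18.73
Hexanal	aldehyde	0.0039	Beany, grassy	55.19	39.57	81.22	59.99	153.63	106.16	56.73
Heptanal	aldehyde	0.0028	Tallow	7.29	7.32	8.50	6.60	12.16	9.05	7.78
Octanal	aldehyde	0.0008	Citrus-like	9.90	12.49	10.32	18.22	16.03	9.29	10.09
Benzaldehyde	aldehyde	0.35	Almond	−	−	36.86	38.77	58.36	36.27	38.91
Phenylacetaldehyde	aldehyde	0.004	Honey	14.17	13.36	15.95	43.37	18.73	13.03	11.06
Nonanal	aldehyde	0.015	Flower, orange	50.85	49.46	28.96	82.06	43.98	23.28	28.55
(E)-2-nonenal	aldehyde	0.00019	Fatty, tallow	9.20	10.48	7.32	9.04	8.64	6.39	5.05
Decanal	aldehyde	0.005	Fatty	12.86	24.20	15.24	20.42	20.23	14.91	17.04
(E,E)-2, 4-octandienal	aldehyde	0.00001		−	−	10.11	18.99	−	−	−
2,4-undecadienal	aldehyde	0.00001		8.29	4.23	8.14	4.42	5.20	5.45	−
3-octanone	ketone	0.057		11.38	17.03	30.45	26.35	24.06	23.21	18.03
2-nonanone	ketone	0.05	Coconut-like	8.67	7.50	6.02	39.41	4.22	4.35	6.66
2-heptanone	ketone	0.14		7.80	10.83	11.96	13.75	16.74	12.60	22.69
Eugenol	phenol	0.0071	Clove	−	23.64	39.99	28.84	28.05	27.28	52.67
4-ethenyl-2-Methoxyphenol	phenol	0.00001		10.22	16.01	11.74	31.36	21.06	17.24	29.35
Isovaleric acid	acid	0.1	Acid, rancid	−	12.90	10.47	9.60	5.79	4.77	−
2-pentylfuran	furan	0.0058	Beany	120.44	75.61	126.84	112.52	93.25	98.25	87.05
2,5-Dimethyl-3-Ethylpyrazine	pyrazine	0.0086	Roast	−	7.14	13.552	36.54	2.91	4.16	−
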