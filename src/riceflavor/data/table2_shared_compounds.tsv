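compound	chem_class	SY1	SY6	SY7	SY8
1-Octen-3-ol	alcohol	2.23	3.69	4.13	4.14
3,4-Dihydroxyphenylglycol	alcohol	2.45	2.19	1.40	0.92
Cyclooctyl alcohol	alcohol	2.31	—	—	5.11
Phenol	phenol	0.26	0.37	—	—
4-(1-Methylpropyl)phenol	phenol	0.95	1.08	1.08	1.20
2-Butyl-2-octenal	aldehyde	2.14	4.33	2.73	—
4-Methyl-3-cyclohexene-1-carboxaldehyde	aldehyde	0.71	1.62	—	2.16
5-Ethylcyclopent-1-enecarboxaldehyde	aldehyde	1.01	—	1.60	—
Benzaldehyde	aldehyde	4.85	—	—	5.09
4-Methylbenzaldehyde	aldehyde	0.46	3.28	2.09	3.52
Nonanal	aldehyde	7.70	9.40	10.00	11.07
trans-2-Octenal	aldehyde	2.70	3.28	2.70	4.80
n-Hexadecanoic acid	acid	1.99	—	0.89	1.09
Tetradecanoic acid	acid	0.36	—	0.40	—
2-Decenal	hydrocarbon	0.71	0.50	—	—
3,3-Dimethylhexane	hydrocarbon	3.20	0.62	1.15	0.70
m-Aminophenylacetylene	hydrocarbon	0.31	—	0.87	0.66
2-Pentadecanone	ketone	1.59	—	0.42	—
2-(Formyloxy)-1-phenylethanone	ketone	3.37	3.74	—	—
Geranylaceton	ketone	2.88	0.58	0.60	1.01
2-(p-Fluorophenyl)-1-methylbenzimidazole	heterocycle	1.70	1.24	—	—
2-Acetyl-1-pyrroline	heterocycle	0.68	2.00	1.63	1.98
2-n-Butyl furan	heterocycle	0.65	—	1.60	1.75
2-Pentyl furan	heterocycle	17.20	22.07	33.53	—
Methoxy-phenyl-oxime	heterocycle	6.97	2.57	4.19	1.99
2-Pentylthiophene	heterocycle	1.18	0.51	1.10	0.65
Ethyl 4-(ethyloxy)-2-oxobut-3-enoate	ester	0.38	0.81	0.68	0.80
Methyl p-(2-phenyl-1-benzimidazolyl)benzoate	ester	0.34	0.63	0.48	—
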