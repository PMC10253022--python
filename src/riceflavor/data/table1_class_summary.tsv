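sample	chem_class	n_compounds	total_content
SY1	alcohol	7	11.79
SY1	phenol	2	1.21
SY1	aldehyde	11	26.79
SY1	acid	2	2.35
SY1	hydrocarbon	11	14.03
SY1	ketone	6	8.85
SY1	ester	8	5.47
SY1	heterocycle	9	29.50
SY2	alcohol	13	26.66
SY2	phenol	2	1.70
SY2	aldehyde	9	26.36
SY2	acid	2	5.11
SY2	hydrocarbon	20	14.75
SY2	ketone	4	3.17
SY2	ester	7	4.65
SY2	heterocycle	5	17.62
SY3	alcohol	9	14.31
SY3	phenol	2	1.17
SY3	aldehyde	7	23.31
SY3	acid	3	16.88
SY3	hydrocarbon	23	12.64
SY3	ketone	4	3.86
SY3	ester	10	8.51
SY3	heterocycle	8	19.32
SY4	alcohol	4	6.37
SY4	phenol	1	0.55
SY4	aldehyde	4	18.02
SY4	acid	2	3.20
SY4	hydrocarbon	15	20.27
SY4	ketone	6	13.81
SY4	ester	10	11.79
SY4	heterocycle	7	25.99
SY5	alcohol	14	14.94
SY5	phenol	2	9.47
SY5	aldehyde	12	23.44
SY5	acid	2	9.50
SY5	hydrocarbon	22	12.93
SY5	ketone	8	13.85
SY5	ester	11	5.01
SY5	heterocycle	7	10.85
SY6	alcohol	6	10.01
SY6	phenol	2	1.45
SY6	aldehyde	7	27.17
SY6	acid	1	0.99
SY6	hydrocarbon	11	11.47
SY6	ketone	9	18.40
SY6	ester	3	2.11
SY6	heterocycle	5	28.40
SY7	alcohol	4	7.81
SY7	phenol	1	1.08
SY7	aldehyde	8	26.55
SY7	acid	2	1.29
SY7	hydrocarbon	7	9.78
SY7	ketone	5	2.65
SY7	ester	5	7.80
SY7	heterocycle	6	43.04
SY8	alcohol	6	12.44
SY8	phenol	2	5.81
SY8	aldehyde	9	38.09
SY8	acid	3	1.78
SY8	hydrocarbon	10	7.13
SY8	ketone	12	26.88
SY8	ester	2	1.49
SY8	heterocycle	4	6.38
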