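retention_time	compound	description
8.9	2-n-Butyl furan	Sweet/floral fragrance
11.2	2-Pentyl furan	Sweet/grass/fruity fragrance
14.5	Nonanal	Floral fragrance/a smell of burnt oil
15.1	1-Octen-3-ol	A smell of earth/grass/sulfur
17.6	2-Acetyl-1-pyrroline	Popcorn fragrance
18.4	cis-Muurola-4(14), 5-diene	Corn fragrance
19.6	2-Butyl-2-octenal	Corn/sweet/floral fragrance
20.7	Methoxy-phenyl-oxime	Floral fragrance
21.3	3-Methylbutyl 2-ethylhexanoate	Roasted/smelly/woody, slightly pungent
22.1	4-(1-Methylpropyl)phenol	Popcorn/corn/cooked rice fragrance
22.6	Geranylaceton	Floral/fresh/fruity fragrance
23.5	Methylcarbamate	Cooked rice fragrance/roasted
24.2	Phenol	Corn fragrance, the smell of earth/grass
24.4	2-Pentadecanone	Sweet fragrance/greasy
26.4	6,10,14-Trimethyl-2-pentadecanone	Creamy/corn/floral fragrance
27.0	4-Hydroxy-2-methylacetophenone	Mango/creamy fragrance
27.6	2,2′,5,5′-Tetramethyl-1,1′-biphenyl	Roasted/burned
29.8	4-Methylbenzaldehyde	Sweet/floral fragrance, slightly sour
30.1	m-Aminophenylacetylene	Floral/creamy fragrance
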