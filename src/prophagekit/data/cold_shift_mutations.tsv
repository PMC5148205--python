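id	locus_tag	gene_product	genome_position	change_in_dna	change_in_protein_or_rna	frequency
M1	SO_0673	Mu phage uncharacterized protein	691074	156 (T→G)	52 (I→M)	0.24
M2	SO_m003	tmRNA (SsrA)	1538151	349	Deletion of U	0.02
M3	SO_2545	Histidine kinase	2679697	669 (C→T)	224 (P→S)	0.12
M4	SO_2545	Histidine kinase	2679698	669 (A→G)	223 (V→V)	0.12
M5	SO_2940	Lambda phage tail fiber protein J	3077206	3267 (G→A)	1089 (Q→Q)	0.19
M6	SO_2940	Lambda phage tail fiber protein J	3077215	3258 (C→A)	1086 (A→A)	0.21
M7	SO_2940	Lambda phage tail fiber protein J	3077236	3237 (A→C)	1079 (A→A)	0.17
M8	SO_3735	Peptidoglycan transglycosylase	3879087	419 (C→A)	140 (A→E)	0.01
M9	SO_3923	Fe hydrogenase maturation rSAM protein	4071260	1113 (T→C)	371 (G→G)	0.13
M10	SO_4717	Tungstate-responsive histidine kinase	4921610	923 (C→G)	308 (S→C)	0.10
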