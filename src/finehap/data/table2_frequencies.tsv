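rsid	variant	position	location	EA_Hap1_2n69	EA_Hap2_2n118	AA_Hap1_2n212	AA_Hap2_2n891	AA_Hap3_2n408	AA_Hap4_2n386	AA_Hap4_asthmatic_hom_2n36
rs150276395	G->A	39908449	GSDMB intron 6	0	0	0.024	0.039	0.042	0.53	0.78
rs8065520	T->C	39915395	GSDMB intron 2	0	0	0.066	0.094	0.270	0.79	0.97
rs73985226	A->G	39920081	Intergenic	0	0	0.024	0.037	0.029	0.50	0.78
rs73985227	G->A	39921437	ORMDL3 3'UTR	0	0	0.024	0.038	0.032	0.52	0.78
rs28623237	T->C	39924694	ORMDL3 intron 3	0	0	0.033	0.062	0.037	0.76	0.94
rs73985229	G->A	39925400	ORMDL3 intron 1	0	0	0.019	0.039	0.029	0.53	0.78
rs113282230	A->T	39927157	ORMDL3 intron 1	0	0	0.019	0.039	0.029	0.53	0.78
rs113571956	A->T	39927234	ORMDL3 intron 1	0	0	0.019	0.039	0.029	0.53	0.78
rs73985230	T->C	39929476	Intergenic	0	0	0.019	0.039	0.027	0.50	0.75
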