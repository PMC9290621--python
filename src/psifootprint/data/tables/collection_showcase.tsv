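strain	antibiotic	hit_genes	ri_genes
KNN 49.3e	Amicetin	88	7
Tü 3180	Griseoviridin/Viridogrisein	50	3
Tü 6430	Pactamycin	45	3
Tü 2975	Pristinamycin	16	1
Tü 2108	Berninamycin	15	2
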