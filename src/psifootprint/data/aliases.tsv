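alias	accession	kind
tuf	TIGR00485	symbol
tufA	TIGR00485	symbol
tufB	TIGR00485	symbol
rrsS	TIGR00233	symbol
translation elongation factor tu	TIGR00485	product
elongation factor ef-tu	TIGR00485	product
translation elongation factor g	TIGR00484	product
tryptophan-tRNA ligase	TIGR00233	product
tryptophanyl-tRNA synthetase	TIGR00233	product
ribosomal protein S12	TIGR00981	product
ribosomal protein S5	TIGR01021	product
ribosomal protein L3	TIGR03625	product
ribosomal protein L4	TIGR03953	product
ribosomal protein L11	TIGR01632	product
ribosomal protein L17	TIGR00059	product
ribosomal protein L22	TIGR01044	product
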