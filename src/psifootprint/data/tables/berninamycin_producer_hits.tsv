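gene	description	duplication	phylogeny	bgc	accession
rpsR	30S ribosomal protein S18	+	+	+	TIGR00165
yciO	tRNA threonylcarbamoyl adenosine modification protein, Sua5/YciO/YrdC/YwlC family	+	+	+	TIGR00057
rpmF	50S ribosomal protein L32	+	+	+	TIGR01031
rpmE	50S ribosomal protein L31	+	+	+	TIGR00105
tufA/B	elongation factor Tu	+	+	6_3	TIGR00485
rpmB	50S ribosomal protein L28	+	-	+	TIGR00009
rpmG	50S ribosomal protein L33	+	-	+	TIGR01023
rpsD	50S ribosomal protein L4	-	-	6_3	TIGR03953
rpsL	30S ribosomal protein S12	-	-	6_3	TIGR00981
rpsJ	30S ribosomal protein S10	-	-	6_3	TIGR01049
rpsO	30S ribosomal protein S15	-	-	+	TIGR00952
rpsG	30S ribosomal protein uS7	-	-	6_3	TIGR01029
fusA	elongation factor G	-	-	6_3	TIGR00484
rrsS	tryptophan-tRNA ligase	+	+	-	TIGR00233
rsgA	ribosome small subunit-dependent GTPase A	+	-	-	TIGR00157
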