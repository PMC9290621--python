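strain	antibiotic	hit_genes	rpsE	rpsL	rplC	rplD	rplK	rplQ	rplV	ri_genes	reference
Actinoplanes friuliensis DSM 7358	Friulimicin	17	-	-	-	-	-	-	-	-	CP006272
Amycolatopsis mediterranei S699	Rifamycin	17	-	-	-	-	-	-	-	-	CP002896
Mycobacterium avium 104	Glycopeptidolipid, Mycobactin	15	-	-	-	-	-	-	-	-	CP000479
Rhodococcus jostii RHA1	Rhodochelin	15	-	-	-	-	-	-	-	-	CP000431
Amycolatopsis orientalis HCCB 10007	Vancomycin	14	-	-	-	-	-	-	-	-	CP003410
Streptomyces brunneus CR22	Feglimycin	14	-	-	-	-	-	-	-	-	NZ_CP034463
Streptomyces violaceusniger Tü 4113	Nigericin	14	-	-	-	-	-	-	-	-	CP002994
Streptomyces chartreusis NRRL 3882	Tunicamycin	13	-	-	-	-	-	-	-	-	NZ_LT963352
Streptomyces parvulus 2297	Actinomycin D Dactinomycin	13	-	-	-	-	-	-	-	-	NZ_CP015866
Streptomyces viridochrom. DSM 40736	Phosphinothricin	13	-	-	-	-	-	-	-	-	GG657757
Streptomyces davawensis JCM 4913	Roseoflavin	12	-	-	-	-	-	-	-	-	HE971709
Streptomyces formicae KY5	Formicamycins A-M	12	-	-	-	-	-	-	-	-	NZ_CP022685
Streptomyces avermitilis MA-4680	Avermectin Oligomycin	11	-	-	-	-	-	-	-	-	NC_003155
Streptomyces bingchenggensis BCW-1	Meridamycin	11	-	-	-	-	-	-	-	-	NC_016582
Streptomyces coelicolor A3(2)	Actinorhodin Undecylprodigiosin	11	-	-	-	-	-	-	-	-	NC_003888
Streptomyces lividans TK24	Actinorhodin Undecylprodigiosin	11	-	-	-	-	-	-	-	-	NZ_GG657756
Streptomyces malaysiensis DSM 4137	Azalomycin F	11	-	-	-	-	-	-	-	-	NZ_CP023992
Streptomyces niveus NCIMB 11891	Novobiocin	11	-	-	-	-	-	-	-	-	NZ_CM002280
Salinispora tropica CNB-440	Salinisporamide A	11	-	-	-	-	-	-	-	-	CP000667
Streptomyces albus DSM 41398	Salinomycin	10	-	-	-	-	-	-	-	-	NZ_CP010519
Streptomyces flavogriseus ATCC 33331	Carbapenem	10	-	-	-	-	-	-	-	-	CP002475
Streptomyces pratensis ATCC 33331	Carbapenem	10	-	-	-	-	-	-	-	-	NC_016114
Thermobifida fusca YX	Fuscachelin	10	-	-	-	-	-	-	-	-	CP000088
Streptomyces clavuligerus ATCC 27064	Tunicamycin	9	-	-	-	-	-	-	-	-	NZ_CP027858
Streptomyces tsukubaensis NRRL 18488	Bafilomycin	8	-	-	-	-	-	-	-	-	AJSZ01000001
Streptomyces fungicidicus TXX3120	Enduracidin	7	-	-	-	-	-	-	-	-	NZ_CP023407
Streptomyces ghanaensis ATCC 14762	Bafilomycin	7	-	-	-	-	-	-	-	-	DS999641
Streptomyces pluripotens MUSC 135	Antimicin	7	-	-	-	-	-	-	-	-	NZ_CP021080
Frankia casuarinae CcI3	Frankiamicin	5	-	-	-	-	-	-	-	-	NC_007777
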