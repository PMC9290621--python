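strain	antibiotic	hit_genes	rpsE	rpsL	rplC	rplD	rplK	rplQ	rplV	ri_genes	reference
Thermus thermophilus HB8	Paromomycin	75	+	+	-	+	+	-	-	4	AP0082
Saccharopolyspora erythraea NRRL 2338	Erythromycin	51	+	+	-	+	+	+	-	5	NC_009142
Micromonospora echinospora DSM 43816	Gentamicin	49	-	+	-	-	-	+	+	3	NZ_LT60748
Kitasatospora setae KM-6054	Kirromycin	48	-	-	+	+	+	+	+	5	AP010968
Sphaerisporangium cinnabarinum ATCC 31213	Dityromycin	47	-	+	-	+	-	-	-	2	QAPD00000000
Micromonospora inyonensis NRRL 3292	Sisomicin	46	-	-	-	-	-	+	+	2	GCA_900091415
Brevibacillus brevis X23	Edeine	43	+	-	-	+	-	-	-	2	NZ_CP023474
Streptomyces roseochromogenus	Anisomycin	42	+	+	+	+	-	+	+	6	NZ_CM0022
Micromonospora carbonaceae	Evernimicin	40	+	-	-	-	-	-	+	2	NZ_CP058322
Streptomyces cattleya DSM 46488	Kirromycin	28	+	+	-	+	-	-	+	4	CP003219
Streptomyces cattleya NRRL 8057	Kirromycin	27	-	+	-	+	-	-	+	3	FQ859185
Rhodococcus erythropolis PR4	Chloramphenicol	24	-	-	-	+	-	-	+	2	AP008957
Rhodococcus pyridinivorans SB3094	Chalcomycin	21	-	+	-	+	-	-	+	3	CP006996
Streptomyces griseochromogenes ATCC 14511	Blasticidin S	19	-	-	-	-	-	-	-	-	NZ_CP0162
Xenorhabdus nematophila SII	Odilorhabdins	19	+	-	-	-	+	-	-	2	NZ_CP060401
Streptomyces kasugaensis AM-2504	Dityromycin	17	-	-	-	-	-	-	-	-	SIXH01000000
Streptomyces rimosus ATCC 10970	Oxytetracyclin	17	-	+	-	-	-	-	-	1	NZ_CP0236
Streptomyces bikiniensis NRRL B-1049	Chalcomycin	15	-	-	-	-	-	-	-	-	JNWL00000000
Streptomyces collinus Tü 365	Kirromycin	15	-	-	-	-	-	-	-	-	CP006259.1
Streptomyces lateritius JCM 4389	Granaticin	15	-	-	-	-	-	-	-	-	BMTO00000000
Kitasatospora aureofaciens DM-1	Chlortetracycline	14	-	-	-	-	-	-	-	-	NZ_CP0205
Streptomyces albulus NK660	Anisomycin	14	-	-	-	-	-	-	-	-	NZ_CP0075
Streptomyces pristinaespiralis PR11	Pristinamycin	14	-	+	-	-	-	-	-	1	CP059696
Streptomyces scabiei 87.22	Bottromycin A2	14	-	-	-	-	-	-	-	-	NC_013929
Streptomyces albireticuli MDJK11	Spiramycin	13	-	-	-	-	-	-	-	-	NZ_CP0217
Streptomyces globosus LZH-48	Factumycin	13	-	-	-	-	-	-	-	-	CP030862
Streptomyces lincolnensis NRRL 2936	Lincomycin	13	-	-	-	-	-	-	-	-	NZ_CP016438
Streptomyces pactum ACT12	Pactamycin	13	-	+	-	-	-	-	-	1	NZ_CP019724
Streptomyces venezuelae ATCC 10712	Chloramphenicol	13	-	-	-	-	-	-	-	-	NC_018750
Streptomyces vietnamensis GIM4.0001	Granaticin	13	-	-	-	-	-	-	-	-	NZ_CP0104
Streptomyces viridochromogenes Tü 57	Avilamycin	13	-	-	-	-	-	-	-	-	NZ_AMLP0000000
Streptomyces xinghaiensis S187	Neomycin	13	-	-	-	-	-	-	-	-	NZ_CP023202
Streptomyces ambofaciens DSM 40697	Midecamycin	12	-	-	-	-	-	-	-	-	NZ_CP012949
Streptomyces chrestomyceticus TBRC 1925	Paromomycin	12	-	-	-	-	-	-	-	-	JAEAGG010000010
Streptomyces pristinaespiralis ATCC 25486	Pristinamycin	12	-	-	-	-	-	-	-	-	CM000950
Streptoverticillium mobaraenses NBRC 13819	Pulvomycin	12	-	-	-	-	-	-	-	-	NZ_CP072827
Streptomyces lavendulae CCM 3239	Streptothricin	11	-	-	-	-	+	-	-	1	NZ_CP024985
Streptomyces lincolnensis NRRL 2936	Lincomycin	11	-	-	-	-	-	-	-	-	NZ_CP0164
Streptomyces antibioticus ATCC11891	Oleandomycin	10	-	-	-	-	-	-	-	-	NZ_CP050692
Streptomyces bottropensis ATCC 25435	Bottromycin A2	10	-	-	-	-	-	-	-	-	NZ_ARTP0000000
Streptomyces laurentii ATCC 31255	Thiostrepton	10	-	-	-	-	-	-	-	-	AP017424
Streptomyces vinaceus NRRL ISP-5257	Viomycin	10	-	-	-	-	-	-	-	-	NRRL ISP-5257
Streptomyces violaceoruber S21	Viomycin	10	-	-	-	-	-	-	-	-	NZ_CP020570
Streptomyces fradiae ATCC 10745	Neomycin	9	-	-	-	-	-	-	-	-	NZ_CP023696
Streptomyces griseus NBRC 13350	Streptomycin	8	-	-	-	-	-	-	-	-	NC_010572
Streptomyces sparsogenes ATCC 25498	Sparsomycin	8	-	-	-	-	-	-	-	-	MAXF00000000
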