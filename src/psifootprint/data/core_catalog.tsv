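accession	symbol	description	is_ri	expected_copies
TIGR00165	rpsR	30S ribosomal protein S18	false	1
TIGR00057	yciO	tRNA threonylcarbamoyladenosine modification protein, Sua5/YciO/YrdC/YwlC family	false	1
TIGR01031	rpmF	50S ribosomal protein L32	false	1
TIGR00105	rpmE	50S ribosomal protein L31	false	1
TIGR00485	tufA/B	elongation factor Tu	false	1
TIGR00009	rpmB	50S ribosomal protein L28	false	1
TIGR01023	rpmG	50S ribosomal protein L33	false	1
TIGR03953	rplD	50S ribosomal protein L4	true	1
TIGR00981	rpsL	30S ribosomal protein S12	true	1
TIGR01049	rpsJ	30S ribosomal protein S10	false	1
TIGR00952	rpsO	30S ribosomal protein S15	false	1
TIGR01029	rpsG	30S ribosomal protein S7	false	1
TIGR00484	fusA	elongation factor G	false	1
TIGR00233	trpS	tryptophan--tRNA ligase	false	1
TIGR00157	rsgA	ribosome small subunit-dependent GTPase A	false	1
TIGR01021	rpsE	30S ribosomal protein S5	true	1
TIGR03625	rplC	50S ribosomal protein L3	true	1
TIGR01632	rplK	50S ribosomal protein L11	true	1
TIGR00059	rplQ	50S ribosomal protein L17	true	1
TIGR01044	rplV	50S ribosomal protein L22	true	1
PSF0001	rpsA	30S ribosomal protein S1	false	1
PSF0002	rpsB	30S ribosomal protein S2	false	1
PSF0003	rpsC	30S ribosomal protein S3	false	1
PSF0004	rpsD	30S ribosomal protein S4	false	1
PSF0005	rpsF	30S ribosomal protein S6	false	1
PSF0006	rpsH	30S ribosomal protein S8	false	1
PSF0007	rpsI	30S ribosomal protein S9	false	1
PSF0008	rpsK	30S ribosomal protein S11	false	1
PSF0009	rpsM	30S ribosomal protein S13	false	1
PSF0010	rpsN	30S ribosomal protein S14	false	1
PSF0011	rpsP	30S ribosomal protein S16	false	1
PSF0012	rpsQ	30S ribosomal protein S17	false	1
PSF0013	rpsS	30S ribosomal protein S19	false	1
PSF0014	rpsT	30S ribosomal protein S20	false	1
PSF0015	rpsU	30S ribosomal protein S21	false	1
PSF0016	rplA	50S ribosomal protein L1	false	1
PSF0017	rplB	50S ribosomal protein L2	false	1
PSF0018	rplE	50S ribosomal protein L5	false	1
PSF0019	rplF	50S ribosomal protein L6	false	1
PSF0020	rplI	50S ribosomal protein L9	false	1
PSF0021	rplJ	50S ribosomal protein L10	false	1
PSF0022	rplL	50S ribosomal protein L7/L12	false	1
PSF0023	rplM	50S ribosomal protein L13	false	1
PSF0024	rplN	50S ribosomal protein L14	false	1
PSF0025	rplO	50S ribosomal protein L15	false	1
PSF0026	rplP	50S ribosomal protein L16	false	1
PSF0027	rplR	50S ribosomal protein L18	false	1
PSF0028	rplS	50S ribosomal protein L19	false	1
PSF0029	rplT	50S ribosomal protein L20	false	1
PSF0030	rplU	50S ribosomal protein L21	false	1
PSF0031	rplW	50S ribosomal protein L23	false	1
PSF0032	rplX	50S ribosomal protein L24	false	1
PSF0033	rplY	50S ribosomal protein L25	false	1
PSF0034	rpmA	50S ribosomal protein L27	false	1
PSF0035	rpmC	50S ribosomal protein L29	false	1
PSF0036	rpmD	50S ribosomal protein L30	false	1
PSF0037	rpmH	50S ribosomal protein L34	false	1
PSF0038	rpmI	50S ribosomal protein L35	false	1
PSF0039	rpmJ	50S ribosomal protein L36	false	1
PSF0040	infA	translation initiation factor IF-1	false	1
PSF0041	infB	translation initiation factor IF-2	false	1
PSF0042	infC	translation initiation factor IF-3	false	1
PSF0043	tsf	elongation factor Ts	false	1
PSF0044	efp	elongation factor P	false	1
PSF0045	prfA	peptide chain release factor 1	false	1
PSF0046	prfB	peptide chain release factor 2	false	1
PSF0047	prfC	peptide chain release factor 3	false	1
PSF0048	frr	ribosome recycling factor	false	1
PSF0049	lepA	elongation factor 4	false	1
PSF0050	typA	GTP-binding translational regulator BipA/TypA	false	1
PSF0051	alaS	alanine--tRNA ligase	false	1
PSF0052	argS	arginine--tRNA ligase	false	1
PSF0053	asnS	asparagine--tRNA ligase	false	1
PSF0054	aspS	aspartate--tRNA ligase	false	1
PSF0055	cysS	cysteine--tRNA ligase	false	1
PSF0056	glnS	glutamine--tRNA ligase	false	1
PSF0057	gltX	glutamate--tRNA ligase	false	1
PSF0058	glyS	glycine--tRNA ligase	false	1
PSF0059	hisS	histidine--tRNA ligase	false	1
PSF0060	ileS	isoleucine--tRNA ligase	false	1
PSF0061	leuS	leucine--tRNA ligase	false	1
PSF0062	lysS	lysine--tRNA ligase	false	1
PSF0063	metG	methionine--tRNA ligase	false	1
PSF0064	pheS	phenylalanine (alpha subunit)--tRNA ligase	false	1
PSF0065	pheT	phenylalanine (beta subunit)--tRNA ligase	false	1
PSF0066	proS	proline--tRNA ligase	false	1
PSF0067	serS	serine--tRNA ligase	false	1
PSF0068	thrS	threonine--tRNA ligase	false	1
PSF0069	tyrS	tyrosine--tRNA ligase	false	1
PSF0070	valS	valine--tRNA ligase	false	1
PSF0071	rsmA	16S rRNA (adenine-N6)-dimethyltransferase	false	1
PSF0072	rsmG	16S rRNA (guanine-N7)-methyltransferase	false	1
PSF0073	rlmN	23S rRNA (adenine-C2)-methyltransferase	false	1
PSF0074	truA	tRNA pseudouridine synthase A	false	1
PSF0075	truB	tRNA pseudouridine synthase B	false	1
PSF0076	trmD	tRNA (guanine-N1)-methyltransferase	false	1
PSF0077	miaA	tRNA dimethylallyltransferase	false	1
PSF0078	era	GTPase Era, 16S rRNA-binding	false	1
PSF0079	obgE	GTPase ObgE, ribosome assembly factor	false	1
PSF0080	rbfA	30S ribosome-binding factor RbfA	false	1
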