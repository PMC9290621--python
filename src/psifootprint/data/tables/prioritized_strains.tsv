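species	dsm_number	hit_genes	rpsE	rpsL	rplC	rplD	rplK	rplQ	rplV	ri_genes
Jiangella alkaliphila	45079	71	+	+	-	+	-	+	+	5
Saccharopolyspora flava	44771	64	+	+	-	+	+	+	-	5
Actinokineospora cianjurensis	45657	57	+	+	-	+	+	-	-	4
Micromonospora aurantiaca	43813	53	-	-	-	+	+	+	+	4
Micromonospora violae	45888	47	-	-	-	+	-	+	+	3
Micromonospora purpureochromogenes	43821	40	+	+	-	-	-	-	+	3
Lentzea albidocapillata	44073	40	+	+	-	-	+	+	+	5
Nocardioides albertanoniae	25218	39	-	+	-	-	+	+	+	4
Actinomadura atramentaria	43919	35	-	+	-	+	-	+	+	4
Geodermatophilus nigrescens	45408	34	-	+	-	-	+	-	+	3
Hoyosella altamirensis	45258	25	+	+	-	+	-	-	+	4
Rhodococcus pyridinivorans	44555	23	+	-	-	+	-	-	+	3
Rhodococcus koreensis	44498	22	-	-	-	+	-	-	+	2
Williamsia marianensis	44944	22	+	-	-	+	-	-	+	3
Rhodococcus kroppenstedtii	44908	20	-	-	-	+	-	-	+	2
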