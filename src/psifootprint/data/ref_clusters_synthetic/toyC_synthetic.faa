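>toyC_synthetic_g1 synthetic toy protein
MCWDYGYSLTAPYLQKCKNASYPLECVMTKVQGTVNHWIRIRRTKYALIVMVYSHRPSWE
IEMEWVALKFSKFHVIGHTDLQRKFKVTHQVQVDAGDIPNWGHPLSNDKVYIKDCFQDPS
YDPYNIHIIYREPNKFMETCRTWHPQVTRPQYRVPWSFTHSKSPLAHNNQIRQNHTEAKV
SPVHHALDFHYNVQMSFYEFYAWLDTQDFSYMCPFEIFFFRFEPKWLWCCNRHLYCCSER
FFEIIHQWRPAARLHKG
>toyC_synthetic_g2 synthetic toy protein
MLQMFWGQMTLISFAKSECKHQARTNGTDHQDVHMTRDPFSNAKCLATNPAPTSRIRHNA
MMELYLIHDEPSRIRSNTLRWWDDPLVHWVFKMFDHQMNLRSTMITTVPDLPTHQQSTAK
IKITSYDTVFCWECQATFLGCYFQNQTGTYNQHTPKFDSCSNYEDCCWRFVQRRMHVFWQ
WAVGRRRFLPFYWYTRICLNSADNMRFCHKVDFESLRDCAPTGNVW
>toyC_synthetic_g3 synthetic toy protein
MLNKPLERPRCLFHSNLDNYPKEVFFYVNAIRRRAEVMLNSFLSAKTWQISCAQWTSCPT
HTYYTQCVCAENVKWKCGMFSVRECVDSHLTHPKHLVDECTGTKGVDQAFGCTYMVQSKM
RAMDNWEDNKAYIQSTKNTHCKQKCFSWCPNTCYEEQCQEVWNAPIMRPPISIMAQQMDQ
YDWPVPTLQIQWHMYMNAWLVPMSIQLSAEFVNANDIDKHHGPHYPSFGQGQEALFDHTK
DNMQMIQRPTCKSSNPYATCWKDIKKKGMKACTDNRVNYRFWNPINESSQNTEKCHESS
>toyC_synthetic_g4 synthetic toy protein
MAVWIQCPDEKDTTTNCKWRWFWKIWPSKKENSNFRVRQARAQYPLPYHSWTTQSKNWGK
DKEITHLMPDWQYKRKQTNASNNDSNRGGKWNASSSNWSVWCGCSTWEFVRLWEMTQALD
SMTEIAICCYGIPNASAASSGQIESQCKPYTWCNEIVTQYYYNQIHWPFHQVHNCWFSHV
YMHCSIVWCNRNLGALEFLKVDTTWTGEPMQHFFAEVEISCANSNWRRGIKTTPQGEMSM
GAARQVYPNNWLF
>toyC_synthetic_g5 synthetic toy protein
MTSGWENKEKEYHGPHWGRFNMMDSRLRNDFLDTKIKSACENHEYTSLCDQTKFLTRFAF
QKPQGEHEQTCITQYINILHFCEYVHERWGPNVCPPVDLTNTHGCNMCEWFVCTTMSNGR
DINGGKTHKWVRPCYVIAYCSWIHPKTNGSALDKEWLHCVAWLEGNLDNMYGFWCAPPFG
GSSCN
>toyC_synthetic_g6 synthetic toy protein
MNEDQWIWDSNMGKCIPNCTNPSYTPTDRSDHYTPAFIFLETGSNQWFDWREYAMIPTAK
NCPEMWTKERGKKDNCYYMINAFNLWGVQWAPDTDEQWHPRIGSWSQCRQCAIISGWLSI
GEPRGCCHLEMCKVVANHWDDHMFVKIKCSLIARFNTSDYMVIGGEFWPSHRIIWGTMIW
YHDDEWFCCFHLPRPRDEMGEDAGKNDQTKQMLRDQMMHAWPWELWSVIHNCFKITGPLM
ERHVTPRPMA
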