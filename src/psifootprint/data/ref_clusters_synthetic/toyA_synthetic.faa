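>toyA_synthetic_g1 synthetic toy protein
MMAPTTYIIFYLHHPYHAQHECQRCKFMWYSQWVVQDLEGIQENGVVRAHITVPMEGGTT
FDCMNLYIYQLRSPQWDRAVKWAENVNCCKNPSGYVRHIHMNPMVCMQIENFDCKRNMFI
KACIWRCHVDARWMEIQAWPKEGIPGRYFKMNNKWDYMCLPMCDANHISYCIYTDQPQLF
YVGMMHRSFHKPTMYNDIWWIMYFACGMTSELRMHRYFFPWLFGPDKIIPVDWT
>toyA_synthetic_g2 synthetic toy protein
MNYLDKRPEIFPHNMTQKSPYHNCAAWTRQHMPDEACKFQAQPHDIHTSLLQEAEDQHRI
HHKYHCKWWGPVEQYYNTKQPFTYSDRLSGKANCEGFMRMLYLIGLLWLEEDDAQNTYRP
HKDGQDSDQPFTCDASYKKIRKYAQIVNDIVQPA
>toyA_synthetic_g3 synthetic toy protein
MCMHSLEIMPMRRHLTEHLLAASDYQYAKMTELCIEQADVIEKFGMAGRWMAQGYFQIKQ
FLPSRRPSWDHLWQIHPIMCDNFETIQRLDPMHYGMVPGFPSIAQWAISRGWCTQRAQPC
DMHTMECEQFRHDPSSMCWAYWMCTHRDRQYSPCQIKTDG
>toyA_synthetic_g4 synthetic toy protein
MTVTTTTLHYVLFRLNFACQKESDCCHMFVQCMKQWHRSILIIKPFHTTDYEDHSQIAST
RTNDMSTSDEYEPEPIFIKPYVQECHLQFDRPPSHIEYFIPYRFPMIVHFQFVHRKVIQG
WPWNRLTFTMCQIPCPNDSCEMERGRVTFPIEAAPICKCSPMAMIWYMPYVQAWWWLHYY
ALLHMIALCCYMHMVDNERVQKATLPWIVKTTGTGSYHNVSG
>toyA_synthetic_g5 synthetic toy protein
MITRKQWEGIKHTVMYGSFCRPFVPHTFEGATYMHEDGGSHHTGEWEDLRRFCLYCFCRG
SEYCNCFDFQMSQCHWLNDWLHMKPQIEMVVHDKEVDAKGLHEHRFQADLCHHDLVQLQW
LWKLANCRLWVWCMEISNAVFGWFQMPECYAA
>toyA_synthetic_g6 synthetic toy protein
MACYATQMEMVEISGCMVDVKGILCYFSFLPQTHFWIFLMTPETENAVHHLCKMGSQVRL
QDVGCDNVDDHAQWNWDDRCQMQFEDCWNNRLNEKLHKWPELFRIVYEYIWEFTGDYRTG
SVEWMWTMGSEFFLANQHCWLDTEWPNFVWKIQCC
>toyA_synthetic_g7 synthetic toy protein
MVAYAMIGDTGKDTVLGIGSSIPDVFEIYCYIGWLQASYSCTSRDLQVIHDQMEPPHDYP
WVADEQMIFNGELKPYNLIIAYNDLYHWVSEKMDGQCCYNFRNAFEFNADRTVAPGVKDF
MHAQEITPEAYPGFPHRHGCACPNCWSPMHKFWY
>toyA_synthetic_g8 synthetic toy protein
MFHRQFIMMGMSRGFTYFMLLYACLANIHYRPCNHMDGMSSSQINVHHITWCYALHWHMC
QFFKRMKPQEQLTMGGYMNCMMAFFAKWEPCWPRSWVIVAPKQLCNYQVPRFNANDVYFT
YYKLPSKQMVCEIMWRDYKLITEYIFYVDANKCNESHKICMHSLGCFKQYRKPVPHIVFW
GLK
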