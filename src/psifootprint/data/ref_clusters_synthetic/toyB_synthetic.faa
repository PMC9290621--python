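>toyB_synthetic_g1 synthetic toy protein
MKHACTPFRSYQYSPGLTLTGPLVDIRIVAGYPQILSGFVHSSTFVGMDWCYVSLSLPYC
SSIFNVSVLNDTIGIFLAFLQQAWFSEMHWAYYGGVPEIRVYRFYYCHSMHKYIDVGVIL
PIPYRTCTTDHVSKAGINPGMPNKYTHMMGAFLMNHARWWGRSDHDQYDHDDSDYLWNFN
YASDKGPPGDNSFHMNSNHMHCNMQWV
>toyB_synthetic_g2 synthetic toy protein
MDCWRFVCRDINQMLRCVCNLRMYRSQKDYDPGGDWRYSKVSTIIRLHPQMSFINFVVHN
WQTCCPRREPWRGEVGWGEELMFLLGWACRCAAVYKHEAMHIKITMKFDDLLNNWGTNDR
HMAGCGWKNPVSETHWETCLIAVCAAQGIWKRRHPIMMGKYYYVM
>toyB_synthetic_g3 synthetic toy protein
MWYYDYDDVYTVGPTLMGTWSADVSDRMLGMSPNDKQQIWEKYEQFGPALQYDIPYPTIT
KYMCQHPVYMEVPHRKNMALRTCTTHKSGYGWMPYWYGIEPCIVSIRPKCQGFVHVFVEI
GWKIKSSGGNNDIDGKLPHKYQKNVKKHGMQMEPDYPSLHTERGHLCPFKLGDWYSDKEW
GQRSEGHTDSSDLKWCTQCSFC
>toyB_synthetic_g4 synthetic toy protein
MACNNFTKEKRQKQQRCIVDGGARWMYQDAHEARRMTMTKGQFIDGLMIFTVYMHFNWIR
MIVLDEKGRMQNNCSKNRNSARRDCPFDANLKPFAPGMSTLAGGPWIAPPNTVCWRHRHQ
FANPIQRVWCETAYYQEKRNKVNGSHSLWLYRNTFHHYQKYPFYAKDNWHLWRVWQSFEF
QQKWNDYTTHRHLCCDMEQIGFSDNKECSWESCWTRCDWTCQREFMVTVMWEYPQNHCQK
KLSWHMSVEVRCLHSAWQ
>toyB_synthetic_g5 synthetic toy protein
MRPYESKRLVRFAPHWRCCHHLKVGFQYYDCTQPSHDMQHTITACAKTGICHSIDFCRKH
QDRSYIFNWIYTTDKKQVIIDYGTDQPGLHDSHYHYLASGMDGPWSMWGAMHHKFMQQIR
CVQLTPCACDYDPGSANCNEDGRRSKQWSSCFGYLMWWAVAPLWHGRFQEVWIFFVGSLP
DNSCNSMNFPEAFWVQKCMVSQCHHAWDTEGSDPYVCRIFFYVDWPTYQVLMPHCMLRYM
GPPACQYGYWAWYYWMGFHIYFKKMTAWNSLSPVMNTM
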