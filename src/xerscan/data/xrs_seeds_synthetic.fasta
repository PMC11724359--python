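>dif xerC=0:11 central=11:17 xerD=17:28
GGTGCGCATAATGTATATTATGTTAAAT
>r27 xerC=0:11 central=11:17 xerD=17:28
AGTACATATAACAAAGATTATGTTAAAT
>cer_like_synthetic xerC=0:11 central=11:19 xerD=19:30
GGTGCGTACAATTAAGGGATTATGGTAAAT
>psi_like_synthetic xerC=0:11 central=11:18 xerD=18:29
GGTGCGCGCAAGATCCATTTATGTTAAAT
>syn_28a xerC=0:11 central=11:17 xerD=17:28
GGTACGCATAAAGTTACTTATGTTAAAT
>syn_28b xerC=0:11 central=11:17 xerD=17:28
AGTGCGTATAATTGCAGTTATGTTAAAT
>syn_29a xerC=0:11 central=11:18 xerD=18:29
GGTGCGCATAAACTTCGATCATGTTAAAT
>syn_30a xerC=0:11 central=11:19 xerD=19:30
TGTACGCATAAGTTTAAGCTTATGTTAAAT
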