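GTGACGCCGTCAC
GTGACGACGTCAC
GTGACGTTGTCAC
GTGGCAATGTCAC
GTGACATTGTCAC
GTGACATTGTTAC
GTGACATTGTCAC
GTGACACTGTCAC
GTGACGACGTCAC
GTTACGTTGTCAC
GTGACACTGTCAC
GTGACATCGTCAC
GAGACGGTGTCAC
GTGACAGTGTCAC
GTGACGCTGTTAC
GTGACAGCGTCAC
GTGTCGGCGTCAC
GTGACGGCGTCAC
GTGACAACGTCAC
GTGACAGCGTCAC
GTGACATTGTCAC
GTGACGATGTCAC
GCGACGACGTCAC
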