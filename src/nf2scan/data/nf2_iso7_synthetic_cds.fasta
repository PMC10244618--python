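>NF2-iso7_synthetic_cds 1521nt back-translated synthetic CDS (most-frequent human codons)
ATGCTGGGCACCGCCCTGTGCGGCAGCTTCGCCCCCAAGACCGAGACCGCCGTGTGCCTG
CTGGACGGCGACAGCTGCGTGCCCATCAGCACCGCCCAGGTGTTCAGCGACAGCGGCAAG
GAGGCCTTCTGCAAGTACTGGGGCGTGCAGCTGAGCCGCAACAAGCGCGACTACCTGCTG
ACCCCCATCCAGGACAACACCGGCGAGTACGTGGACGCCAAGAACCACGACGCCACCGAG
AGCGGCGTGGTGGCCATGACCAACCTGAGCGCCAAGAAGCCCCTGAGCACCGACCCCGAG
ATCGGCGCCAGCTTCGCCCACAGCATCAACAACGACCGCGTGCGCGACAGCGAGAACATC
CAGCTGTACCTGACCAACAGCCAGAACTGCCTGTTCTACCCCGTGGAGCACTACGCCACC
GACAACGCCCTGAGCGAGAAGCTGAGCCTGCTGATCGTGGACGCCCTGGGCCTGATCGTG
TACACCGAGAACAAGCGCCTGCCCCCCGTGCTGGCCTTCCCCTGGGAGGAGATCAACGAC
GAGAGCAGCCTGATCCTGCTGCGCAAGATCCCCGACCTGGCCGGCGCCAAGGGCAGCATC
GGCCCCCTGGTGCAGACCTACGGCGTGAAGTGCCCCCTGTGGTTCATGTGCAGCGCCAAC
CACGAGCCCCTGATGCTGGTGGGCAAGGTGCGCCGCTGGATCGAGAGCACCTTCAGCAAG
GACCGCAACTTCGAGCTGCAGCTGAAGCTGCTGTGGATCCTGAGCCTGTGGCCCGAGGGC
GACTGGCGCGCCTACACCACCCGCGCCGACGAGGCCGCCCGCATCCAGAGCCGCAACCCC
GGCAACCCCGAGAGCATCATCCAGGTGGGCATGTTCCAGGACACCAACTTCCAGAACAAG
GAGCTGAAGGAGTTCGTGGTGAACGGCGAGATCACCAAGAGCGAGATCGTGGAGTACGTG
TACCGCACCAGCGACCGCGAGTGCCTGTACAGCCACGCCACCAAGGTGCACAGCGGCTGG
AACCTGGACAACTACAAGCTGGTGGAGGAGCGCGAGAGCCACACCGGCCCCGCCAGCCTG
TGGTTCAGCCACACCGAGGAGCCCAGCATCGTGGTGCCCACCCTGAGCAGCGGCCCCTGG
GGCATCGAGAAGGGCCTGTACAAGCCCGAGCTGACCAAGGACAGCTTCACCTACCCCTGC
AGCAACTTCTACGACCTGTGGATCGGCATCGCCCTGCTGGAGATCGCCACCCCCCAGGGC
AGCCTGATCGAGGAGGACCACCTGGTGGCCCACATGATCACCAGCAGCAGCTTCACCGAG
ATCACCGGCGGCTACGCCCTGCACGACCGCACCCTGCGCAAGGTGATGAGCATCGACAAC
AGCAACTACAAGGTGCACGACCTGATCATCCACGACACCAAGCCCCACGTGGGCGAGGCC
GCCGGCAACCTGCAGCACGGCATCAAGCGCAGCCTGAGCCACGACAGCCCCCAGGCCCAG
GGCCGCCGCCCCATCTGCATC
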