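>SIM0001
CAAGAGTGTCANCTGGATCCCNTACATTCCATTCATGGTACTCCCAGCAAGAAANCCCTT
CCACACAACTCGTCGTTAATGGATGGTCTACATCACGTAACCCAACCGCTACACGGTTAC
AATGATGCGCCCGGCTACCTATGAAGCGCGACGGTCATCCGGTACAGATATTGGAAGACG
TTCGGACCAAACCGGACAACACGGCTCCAAGGCTGCGATCGCGAAGCTTTCTGCATTACT
TGTATCTACAACTCAGTCATGGGATGACCCGTTGGAGGCTCAGGCGTTTTAGCTAGGTTA
CGCTCAGACATCTCCCGCAGAGCAACTTCTGTGTTAGTCAGACTGCTGAAACTAAACGTT
GTAGTCTGGTGCAATTCTCGGTGGCGGATGTTGAAACCCCCTGTGACAGTAGATTACGTA
TTTCGACCTGAGTCAGTTCACCTAAGGAGACTCTTCACTTTGCATGCCCGCCTAATAAAT
GATGCTAATGTCAGAGGGCGAAGGTTCCAGTCGCCCGAATTTCGCCAGTTGCATTCGTCT
CTCCATGGTTGTCGTTGCATATCAGCATGCTCGCGTCTTAGGCCGATACCGAGTATACGT
TGCGCCTTGATGTGTTCGTGTCGCAGGAATAGAATCGCTATGAGAGGGAATCGATGCA
>SIM0002
CAAGAGTGTCAACCGGGTCCCGTACATTCCATTCATGGTACTCCCAGCAAGAAAGCCCTT
CCACACAACCCGTCGTTAATGGATGGTCTACATCACGTAACCCAACCGCTACACGGTTAC
AATGATGCGGCCGGCTACCTATGAAGCGCGACGGTCATCCGGTACAGATATTGGAAGACG
TTCGGAGCAAACCGGACAACACGGCTCCAAGGCTGCGATCGCGAAGCTTTCTGCAGTACT
TGTATCTACAACTCAGTCATGGGATGACCCGTTGGAGGCTCAGGCGTTTTAGCTAGGTTA
CGCTCAGACATCTCCCGCAGAGCAA
>SIM0003
CAAGAGTGTCAACTGGGTCCCGTACATTCCAGTCATGGTACTCCCAGCAAGAAAGCCCTT
CCACCCAACTCGTCGTTAATGGATGGTGTACATCACGTAACCCAACCGCTACACGGTTAC
AATGNTGCGCCCGGCTACCTAAGAAGCGCGACGGTCATCCGGTACAGATATTGGAAGACG
TTCGGAGCAAACCGGACAACACGGCTCCAAGGCTGCGATCGCGAAGCTTTCTGCAGTACT
TGTATCTACAACTCAGTCATGGGATGACCCGTTGGAGGCTCAGGCGTTTTAGCTAGGTTA
CGCTCAGACATCTCCCGCAGAGCAACTTCTGTGTTAGTCAGACTGCTGAAACTAAACGTT
GTAGTCTGGTGCAATTCTCGGTGGCGGATGTTGAAAACCCCTGTGACAGTAGATTACGTA
TTTCGACCTGAGTCAGTTCACCTAAGGAGTCTCTTCACTTTGCATGCCCGCCTAATAAAT
GATGCTAATGTCAGAGAGCGAAGGTTCCAGTCGCCCGAATTTCGCCAGTTGTATTCGTCT
CTCCATGGTTGTCGTTGCCTATCAGCATGCTTGCGTCTTAGGCCGATACCGAGTATACGT
TGCGCCTTGATGTGTTCGTGTCGCAGGAATAGAATCGCTATGAGTGGGAATCGATGCA
>SIM0004
CAAGCCTGTCAACTGGGTCCTGTACATTTCATCCATGGTACCCCCAGCAAGAAAGCCCCT
CCGCACAACTCGTCGTTAATANATGGTCTACATCACGTAACCCAACTGCTACACGGTTAC
AATGATGCGCTAGGCTACCCATGAAGCACGAGGGTCAGTCGGTACAGATATTGGAAGACG
TTCGGAGCAAGCCGGACAACACGGCTCCAAGGCCGCCATCGCGAAGCCTACTGCAGTACT
TGTATCTACAACTCAGCCATGGGATGACCCGTTGGAGGCTCTGGCGTTTTAGCTAGGTTA
CGCTCAGACACCCCTCGCAGAGCAACTTCTGTTTGAGTCAGACTGCTGACGCTAAACGTT
GTAGTCTGGTGCAATCCTCGGTGGCAGATGTTGAAACCTCCTGCGACAGTAGATTACGCA
TTTCAACCTGAGCCAGTTCACCTAAGGAGTCTATTCACTTTGCATGCTCGCCTAACAAAT
GATGCTAATGTCAGAGGGCGAAGGTTCGGGGCGCCCGAATATCGCCAGTTGTATTCGTCT
CTCCATGGGTTTCCTTGCACACCAGCATGCTCGCGCCTAAGGTCGATACCGAGTATACGG
TCAGCCTTGATGTGTTCGTGTCGCAGGAATAGAAGTGCTATGACTGGGAATCGGTTCA
>SIM0005
CAAGCCTGTCAACTGGGTCCTGTACATTTCATCCATGGTACCCCCAGCAAGAAAGCCCTT
CCGCACAACTCGTCGTTAATAGATGGTCTACATCACGTAACCCAACTGCTACACGGTTAC
AATGATGCGCTAGGCTACCCATGAAGCACGAGGGTCAGTCGGTACAGATATTGGAAGACG
TTCGGNGCAAGCCGGACAACACGGTTCCAAGGCTCCGATCGCGAAGCCTTCTGCAGTACT
TGTATCTACAACTCAGCCATGGGATGACCCGTTGGAGGCTCAGGCGTTTTAGCTAGGTTA
CGCTCAGACAGCCCTCGCAGAGCAACTTCTGTTTGAGGCAGAGTGCTGACGCTAAACGTT
GTAGTCTGGTGCAATCCTCGGTGGCAGATGTTGAAACCTCCTNCGACAGTAGATTACGTA
TTTCAACCTGAGCCAGTTCACCTAAGGAGTCTATTCACTTTGCATGCTCGCCTAACAAAT
AATGCTAATGTCAGAGGGCGAAGGTTCGGGGCGCCCGAATATCGCCAGTTGTATTCGTCT
CTCCATGGGTTTCCTTGCACACCAGCATGCTCGCGTCTAAGGTCGATACCGAGTATACGG
TCAGCCTTGATGTGTCCGTGTCGCAGGAATAGAAGCGCTATGACTGGGAATCGATGCA
>SIM0006
CAAGCCTGTCAACTGGGTCCTGTACATTTCATCCATGGTACCCCCAGCAAGAAAGCCCCT
CCGCACAACTCGTCGTTAATAGATGGTCTACATCACGTAACCCAACTGCTACACGGTTAC
AATGATGCGCTAGGCTACCCATGAAGCATGAGGGTCAGTCGGTACNGATATTGGAAGACG
TTCGGAGCAAGCCGGACAACACGGCCCCAAGGCTGCGATCGCGAAGCCTTCTGCAGTACT
TGTATCTGCAACTCAGCCATGGGATGACCCGTTGGAGGCTCAGGCGTTTTAGCTAGGTTA
CGCTCAGACTGCCCTCGCAGAGCAACTTCTGTTTGAGTCAGACTGCTGACGCTAAACGTT
GTAGTCTGGTGCAATCCTCGGTGGCAGATGTTGAAACCTCCTGCGACAGTAGATTACGTA
TTTCAACCTGAGCCAGTTCACCTAAGGAGTCTATTCACTTTGCATGCTCGCCTAACAAAT
GATGCTAATGTCAGAGGGCGAAGGTTCGGGGCGCCCGAATATCGCCAGTTGTATTCGTCT
CTCCATGGGTTTCCTTGCATACCAGCATGCTCGCGTCTCAGGTCGATACCGAGTATAAGG
TCAGCCTTGATGTGTTCGTGNCGCAGGAATAGAAGCGCTATGACTGGGAATCGATGCA
>SIM0007
CAAGAGTGTCAACGGGGTTACCGACACTTCATCCGTGATACTCCAATCAAGAAAGCCTCT
CCGCGCAAGGCTTCGTGAATAGAGGGCCTGTATTACGTAACGCATCAGCTGGGCGGTTAC
AATGATACGCTAGGCTACTCAAGGAGTATTAGGGTCACTCGGTACAGATACTGGAAGACG
TTAGCAGCAAGCCGGGGAACAAGGCTCCGAAGCTGCGACCGCAAGGCCTTCTGCAGCACT
TGTATTTACATCTTAGTCATGCGAGGACCCGTCGGGGGCTCAGGCGTCTTACCTGACTTA
CGCTCAGACACCTCCCGCATTGCAACTTCTGTGTGAGCCGAGCTCCTGAAGTTAGAGTCT
GTGGTCTGGTGCAATGCTCGCCGGCGGAAGTTGAACCCACTTGTGACAGTTGATTACTCA
TTTCAACCCGAATCAGTTCAACGAAAGAGCTTCTTCACATTACACACCCGCCTAATAAAT
GATGCATATGTCAGAGGCCAATTGTTCGGGATGTCCGAATTTCGCCAGTGGCATTCGCCT
CTCCATAGGTTTCGTTGCATACCAGCATGCACGCGCTTNGGGCCGACACCAAGTATCCTT
TCATCGTTCCTGTATTCGTGTCGTAGAAGTAGACGCGCCATGAGTGGGAATTGATGCA
>SIM0008
CAAGGGTGTGAACGGGGTTACCGCCATTTCATCCGTGATACTCCTGGGAAGAAAGCCCCT
CCGCGCAAGTCGTCGTGAATAGAGGGCCTATATTACGTAACGCATCAGCTGGGCGGTTAC
AATGATACGCTAGGCTACCCAAGGAGTGTTAGGGTCACTCGGTACAGATACTGGAAGACG
TTCGCGGCAAGCCGGGGAACAAGGCTCCGAGGCTTCGACCGCAAGGCGTTCTGCTGTACT
TGTATTTACAACTTAGTCATGCGAGGACCCGTTGGGGGCTCAGGCGTCTTACCTGACTTA
CGCTCAGACACCTCCCGCATCGCGACTTCTGTGTGAGCCGGGCTCCTGAAGTTAAAGTCT
GTGGTCTGGTGCAATCCTTGGCGGCGGAAGTTGAACCCACCTGTGACAGTTGATTGCTTA
TTTCAACCTGGGTCAGTTCAACGAAGGAGCCTCTTCACTTTTCACACCCGCCCAATAAAT
GATGCTAATGTCAGAGGCCAACTGTTCGGGTTGTCCGAATTTCGCCAGTTGCATTCGCCT
CTCCATGGGTTTCGTTGCATACCAGCATGCAGGCGCTTAGGGCCGTCACTAAGTATCCTT
TCAGCGTTGCTGTGTTCGTATCGTAGAAGTAGACGCGCCATGAGTGGGAATCGATACA
>SIM0009
CAAGAGTGTCAACGGGGTTACCGACATTTCATCCGTGATACTCCAATCAAGAAAGCCTCT
CCCCGCAAGGTGTCGTGAATAGAGGGCCTGTATTACGTAACGCATCAGCTGGGCGGTTAC
AATGATACGCTAGGCTACTCAAGGAGTATTAGGGTCATTCGGTACAGATACTGGAAGACG
TTAGCAGCAAGCCGGGGAACAAGGCTCCGAAGCGGCGACCGCGAGGCCTTCTGCAGCACT
TGTATTTACAACTTAGTCATGCGAGGACCCGTCGGTGGCTCAGGCGTCTTACCTGACTTA
CGCTCAGACACCTCCCGCATTGCAANTTCTGTGTGAGCCGAGCTCCTGAAGTTAGAGTCT
GTGGTCTGGTGCAATGCTCGCCGGCGGAAGTTGAACCCACCTGTGACAGTTGATTGCTCA
TTTCAACCCGAATCAGTTCAACGAAAGAGCTTCTTCACATTACACACCCGCCTAATAAAT
GATGCTTATGTCAGAGGCCAATTATTCGGGATGTCCGAATTTCGCCAGTGGCATTCGCCT
CTCCATAGGTTTCGTTGCATACCAGCATGCACACGCTTAGGGCCGACACCAAGTATCCTT
TCATCGTTCCTGTGTTCGTGTCGTAGAAGTAGACGCGCCATGAGTGGGAATTGATGCA
>SIM0010
CAAGAGTGTCAACGGGATTACCGACATTTCATCCATGATACTCCAAGCAGGCAAGTCCCT
CTGCGCAAGTCNTCATTAATAGAGGGCCTATATCATGCAACTTATCAGCTGGACGGTTAC
AATGATACGCTAGGCTACCTAAGGAATGTTAGGGTCGCCCGGCACAGATACTGGAAGACG
TTCGGAGCAAGCCGGGCGACAATACTCCGAGGCTGCGACCGCCAAGCCTTCNGCAATACT
TGTATTTACAACTTAGTCATGCGAGGACCCGTTGGGGGCTCAGGCGTCTTACCTAACTTA
CTCTCAGACACCTCCCGCAGCGCAA
>SIM0011
CAAGAATGTCAACGGGATTACCGACATTTCATCCATGATACTCCAAGCAGGAAAGTCCCT
CTGCGCAAGTCGTCATTGATAGAGGGCCTATATTATGCAACTCATCAGCTGGACGGTTAC
AATGATACGCTAGGCTACCTAAGGAATGTTAGGGTCGCTCGGCACAGATACTGGAAGACG
TTCGGAGCAAGCCGGGCGACAATGCTCCGAGGCTGCGACCGCGAGGCCTTCTGCAATACT
TGTATTTACAACTTAGTCATGCGAGGACCCGTTGGGGGCTCAGGCGTCTCACCTAACTTA
CTCTCAGACACCTCCCGCAGCGCAACTTCTGTGTGAGCCAGACTATTGAAGTTAAAGTCT
GTGGTCTGGTGCGATCCTCGGCGGCGGAAGTTGAAGCCACCTGTNACGGTAGATTACTCA
TTTCAACGTGAGTCAATTCAACGAAGGAGTTTCTTGATTTTGCACACCCGCCTTATAAAT
GATGTTAATGTCAGCGGCCAAATGTTCGGGTCGTCCGAATTTCGCCAGTTGTATTCGCCT
CTCCATGGTTTTCGTTGCATACCAGCATGCACACGCCTAGGGCCGATACCAAGTATACTT
TCATCGTTGCTGTGTTTGTGTCGTAGGAGTAGAAGCGCCATGAGTGGGAATCGATGCA
>SIM0012
CAAGAGTGTCAACGGGATTACCGACATTTCATCCATGATACTCCAAACAGGAAAGTCCCT
CTGCGCAAGTCGTCATTAATAGAGGGCCTATATTATGCAACTCTTCAGCTGGACGGTTAC
AATGATACGCTAGGCTACCTAAGGAATGTTAGGGTCGCTCGGCACAGATACTGGAAGACG
TTCGGGGCAAGCCGGGCGACAATACTCCGAGGCTGCGACCNCGAGGCCTTCTGCAATACT
TGTATTTACAACTTAGTCATGCGAGGACCCGTTGGGGGCTCAGGCGTCTTACCTAACTTA
CTCTCAGACACCTCCCGCAGCGCAACCTCTATGTGAGCCAGACTATTGAAGTTAAAGTCT
GTGGTCTGGTGCGATCCTCGGCGGCGGAAGTTGAAGCCACCTATGACGGTAGATTACTCA
TTTCAACGTGAGTCAATTCAACGAAGGAGTTTCTTGATTTTGNACACCCGCCTTATAAAT
GATGCTAATGTCAGCGGCCAAATGTTCGGGTCGTCCGAATTTCGCCAGTTGTATTCGCCT
CTCCATGGGTTTCGTTGCATACCAGCATGCACACGCCTAGGGCCGATACCAAGTATACTT
TCATCGTTGCTGTGTTTGTGTCGTAGGAGTAGAAGCGCCATGAGTGGGAATCGATGCA
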