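>SIM0001
AGGATCGAGGCCTTGGTAAAACCTCTGCTGCATGAGGCGCTGATATACGGGCATACGCCC
GTTCTACTACCTTGCTATGGGTATATAAATCTGTTGCAAGGTTTGGTTACCGTTCGCCCA
ATGCATGAAACTGGCACCCCNTTTCGAGATGGCATCGCATGGCAGGTTTGTTCATGCCGG
AACATCGTATTTCCCCCTAATCGGTCCAAAACAGTCCGACCGTGACACACAATACTCCTT
GATCGATACGCGGCACCTCTTGCCAGGCTAGTAGCTCACCTCAAGTGGGCCCCTAAAAAC
CATCCGTCTTCCAGCCTTAGGAAAT
>SIM0002
AGGATCGAGGCCTTGGTAAAACCTCTGCTGCGTGAGGCGCTGATATACGGGCATACGCCC
GTTCTACTACCTTGCTATGGGTATATAAATCTGTTGCAAGGTTTGGTTACCGTTCGGCCA
ATGCATGAAACTGGCACCTCATTTCGAGNTGGCATCGCATGGAAGGTTTGTTCATGCCGA
AACATCGTATTTCCCCCTAATCGGTCCAAAACAGTCCAACCGTGACACACAATACTCCTG
GATCGATACGCGGGACCTCTTGCCAGGCTAGTAGCTCACCTCAAGTGGGCCCCTAAAAAC
CATCCATCTTCCAGCCTCAATAAATTGGGACTATCCTGTTGGATGGGAGCCTTACAACCG
AAACCGGCTTCGGGTTGGCAGCAGTCCGAGACTGACAGTAGTCGCCACAGTGACACTACC
GCTTTGTGTGACTTCGTCCGGACCTCTTTCGGGCACCGACTAAAAGTCGTAGGTCGGTGG
TTGTCACAATTTGTGACTCATGAAGTTTGTAAAGCAACTGTCCTGAGTTGAGAAGGTCAT
AAAGCCAATTTTCTTGTAGACCGTCTGCTTTGGCGCACTTGTTGGCANACTCTAATGTAT
GAGGAAAATGGGAGTATCACTAAGACCGGTGTTTTGACAATTACACTCTGTGCTGAAA
>SIM0003
AGGATCGAGGCCTTGGTAAAACCTCTGCTGCGTGAGGCGCTGATATACAGGCATACGCCC
GTTCTACTACCTTGCTATGGGTATATAAATCTGTTGCAAGGTTTGGTTACCGTTCGCCCA
ATGCATGAAACTGGCACCTCATTTCGAGATGGCATCGCATGGAAGGTTTGTTCATGCCGG
AACATCGTATTTCCCCCTAATCGGTCCAAAACAGTCCAACCGTGACACACAATACTCCTG
GATCGATACGCGGGACCTCTTGCCAGGCTAGTAGCTCACCTCAAGTGGGCCCCTAAAAAC
CATCCGTCTTCCAGCCTCAGGAAATTGGGACTATCCTGATGGATGGGAGCCTTACAACCG
AAACCGGCTTCGGGTTGGCAGCAGTCCGAGACTGACAGTAGTCGCCACAGTGACACTACC
GCTTTGTGTGGCTTCGTCCGGACCTCTTTCGGGCTCCGACTAAAAGGCGTAGGTCGATGG
TTGTCACAATTTGTGACTCATGAAGTTTGTAAAGCAACTGTCCTGAGTTGAGAAGGTCAT
AAAGCCAGTTCTCTTGTAGATCGTCTGCTTTGGCGCACTTGTTGGCACACTCTAATGTAT
GAGGAAAATGGGAGTATCACTAAGACCGGTGTTTTAACAATTACACTCTGTGCTGAAA
>SIM0004
AGAATCCAGACCGTGGTAAAACCCCGGCTGCGTAAGGCACTGACATACGGGCATACGCCC
GTTCCACTACATTCCTATGGGTATATAAATCAGTGGCAAGGTCTGGTTGCCGTTCGCCCA
ACGCATGAAACCGACACCTCATTTCGAGATGGCATCGCATGGAAGGTTTGTTCATGCCGG
AGCATCGTATTTCCCCCTGACCCTTCCAAAACAGTCCAACCGTGACACAAAATACTCCTG
GGCCGATACGTGGGTCCTTTTCCCGGACNAGTAGCTCGCCTCAAGTGAGCCCCTAAAAAC
CATGCGTCTTCCAGCTTCAGGACATTGGGAGTATCCTGTTGGATTAGAGCCATTCAACTG
AAATCGGCTTCGGGTTGGCAGCAGCCCGAGACTGACAGTAGTCACCACAATGACACTACC
ACTCTGTGTAACTTCATCCAGACCTCTTTCCGGCTCCAACTAAAAGTCGTAGGTCGATGG
CTGTCACAATTTGGGACTCATGAAGATTGCAAAGCAACTGTTCTGGGTTGAGAAAGCCAT
AAAGCCATTTACCTCGTAGACTGTCTGTTTTGGCGCGTTTGTAGGTGCCCTCAAATGTAT
AAGGAGAACNGGATTATCACTAGGACCGATGTTTTGACAATTACACTCTGCGGTGAAA
>SIM0005
AGGATCCAGACCGTGGTAAAACCCCTGCTGCGTGAGGCACTGACATACGGGCATACGCCC
GTTCCACTACCTTCCTATGGGTATATAAATCTGTGGCAAGGTCTGGTTGCCGTTCGCCCA
GCGCATGAAACCGACACCTCATTTCGAGATGGCATCGCATGGAAGGTTTGTTCTCGCCGG
AACATCGTACTTCCGCCTGACCCTTCCGAAACAGTCCAACCGTGACAAAAAATACTCCTG
GACCGATACGTGGGTCCTTTTCCCGGGCTAGTAGCTCGCCTCAAGTGGGCCCCTAAAAGC
CATCCGTCTACCAGCTTCAGGAAATTGGGAGCATCCTGTTGGATTGGAGCCACTCAACTG
AAATCGGCTTCTGGTTGGCTGCAGCCCGGGATTAACAGTAGTCGCCACAATGACACTACC
GCTTTGTGTAACTTCATCCAGGCCTCTTTCGGGCTCCAACTAAAAGTCGTAGGTCGATGG
CTGTCACAATTCGGGACTCATGAAGATTGCAATGCAACTGTCCTGGGTTGAGAAAGCCAT
AAAGCTAGTTACCTCGTAGACCGTCTATTTTGGCGCGTGTGTTGGTACCCTCAAATGTAT
AAGGAAAATCGGATTATCACTAGGACCGATGTTTTGACAATTATACCCTGCGGTGAAA
>SIM0006
AGAATCCAGACCGTGGTAAAACCCCGGCTGCGTGAGGCACTGACATACGGGCATACGCCC
GTTCCACTACATTCCTATGGGTATATAAATCAGTGGCAAGGTCTGGTTGCCGTTCGCCCA
ACGCATGAAACCGACACCTCATTTCGAGATGGCATCGCATGGAAGATTTGTTCATGCCGG
AACATCGTATTTCCCCCTGACCCTTCCAAAACAGTCCAACCGTGACACAAAATACTCCTG
GGCCGATACGTGGGTCCTTTTCCCGGGCTAGTAGCTCGCCTCAAGTGAGCCCCTAAAAAC
CATGCGTCTTCCAGCTTCAGGACATTGGGAGTATCCTGTTGGATTAGAGCCNTTCAACTG
AAATCGGCTTCGGGTTGGCAGCAGCCCGAGACTGACAGTAGTCGCCACAATGACACTACC
ACTCTGTGTAACTTCATCCAGACCTCTTTCGGGCTCCAACTAAAAGTCGCAGGTCGATGG
CTGTCACAATTTGGGACTCATGAAGATTGCAAAGCAACTGTTCTGGGTTGAGAAAGCCAT
AAAGCCATTTACCTCGTAGACTGTCTGTTTTGGCGCGTTTGTAGGTGCCCTCAAATGTAT
AAGGAGAATTGGATTATCACTAGGACCGATGTTTTGACAATTACACTCTGCGGTGAAA
>SIM0007
AGGATCCAGGGCTCGGTAAAGCCTCTGCTGTGTAAGGTGCTGGCGTGCGGGTATACGACC
GTTCTGCTACCCTACTATGGGTACATAAATCTGTTGCAGAGTCTGGTTTCCGTNTGTTTA
TCACATGAAACTGACACATCATTCCGAGATGGCATCGCATGGAAGGTTTATTCATGCCGG
AACATCGTATCCCCCCCCAACCCGTCCAAGTGAGTCCAACCATGACACACAGTGCTTCTA
ACTCGAGACCGGGGTCCTTTTGCCGGTCTAGCGATTCGCCTAAAGTGGATCCCTAAAAAC
CGTCCGTCTTCCAGCTTCAGGAGAGTGCCAGTATCCTCTTGGATGGGAGCCATTCAACCA
AAAGCGCCTTTCGATTGGCAGCGGTCGGAGATTGGTAGTAGTCGCCAAAATTACACTACC
GCTCTGTGTAGCGTCGTCCAGACCTCTTTCGGACTCCAACTAAAAGCCGTGAGTCGATGG
CTGTCGAAATTTGTGACTCATGAAGTTCGCAAAGCAACTACCCTGAGTCGAGAGGGCCAT
AAAACCATCTCCCTTGTAGACCGTCTGTCTTGGCGGGTTTGTTGGTACCCTCTAATGTAT
AAAGAAGATGGGGGTATCCCTAGAGCCGGTGCTTTGACAGTAACGCTCTGCCCTAATA
>SIM0008
AGGATCCAGGGCTCGGTAAAGCCTCTGCTGTGTAAGGTGCTGGCGTGCGGGTATACGACC
GTTCTGCTACCCTACTATGGGTACATAAATCTGTTGCAGAGTCTGGTTTCCGTTTGTTTA
TCACATGAAACTGACACATCATTCCGAGATGGCATCGCATGGAAGGTTTATTCATGCCGG
AACATCGTATCCCCCCCCAACCCGTCCAAGTGAGTCCAACCATGACACACAGTGCTTCTA
ACTCGATACCGGGGTCCTTTTGCCGGTCTAGCGATTCGCCTAAAGTGGATCCCTAAAAAC
CGTCCGTCTTCCAGCTTCAGGAGAGTGCCAGTATCCTCTTGGATGGGAGCCATTCAACCA
CAAGCGCCTTTCGATTGGCAGCAGTCGGAGATTGGTAGTAGTCGCCAAGATTACACTACN
GCTCTGTGTAGCGTCGTCCAGACCTCTTTCGGACTCCAACTAAAAGCCGTGAGTCGAAGG
CTGTCGAAATTTCTGACTCATGAAGTTTGCAAAGCAACTACCCTGAGTCGAGAGGGCCAT
AAAACCATCTCCCTTNTAGACCGTCTGTCTTGGCGGGTTTGTTGGTACCCTCTAATGTAT
AAAGAAGATGGGGGTATCCCTAGAGCCGGTGCTTTGACAGTAACGCTCTGCCCTAATG
>SIM0009
AGGATCCAGGGCTCGGTAAAGCCTCTGCTGTGTAAGGTGCTGGCGTGCGGGTATTCGACC
GTTCTGCTACCCTACTATGGGTACATAAATCTGTTGCAGAGTCTGGTTTCCGTTTGTTTA
TCACATGACACTGACACATCATTCCGAGATGGCATCGCATGGAAGGTTTATTCATGCTGG
AACATCGTATCCCCCCCCAACCCNTCCAAGTGAGTCCAACCATGACACACAGTGCTTCTA
ACTCGATACCGGGGTCCTTTTGCCGGTCTAGCGATTCGCCTAAAGTGGATCCCTAAAAAT
CGTCCGTCTTCCAGCTTCAGGAGAGTGCCAGTATCCTCTTGGATGGGAGCCATTCAACCA
AAAGCGCCTTTCGATTGGCGGCAGTCGGAGATTGGTAGTAGTCGCCAAAATTACACTACC
GTTCTGTGTAGCGTCGTCCAGACCTCTTTCGGACTCCAACTAAAAGTCGTGAGTCGACGG
CTGTCGAAATTTGTGACTCATGAAGTTTGCAAAGCAACTACCCTGAGTCGAGAGGGCCAT
AAAACCATCTCCCTTGTAGACCGTCTGTCTTGGCGGGTTTGTTGGTACCCTCTCATGTAT
GAAGAAGATGGGGGTATCCCTAGAGCCGGTGCTTTGACAGTAACGCTCTGCCCTAATA
>SIM0010
AGGATCCAGGCCTTGGTAGAACCTTTGCTGTATAAGGAGCTGGCGTGCGGGCATACTCCC
GTTCTGCTACCATACTATGGGAACATAAGTCTGTTGCAGGGTCTGGTTTGCGTTCGTTCA
TCACATGAAGCTAACACCTCGTTTCGAGATGCCATGGCATGGAAGATTTATTTATGCCGG
AACACCGTGTCTCCCCCTAACCCGTCCAAGTCAGTCCAACCTTGACACACAGTGCTCCTA
ACTTGATACCGGGGTCCTTTTGCCGGCCTAGCGGTTGGCCTAAAGTGGATGCCTCAAAAC
CGTCCGTCTTCCAACTTCAGGAGAG
>SIM0011
AGGATCCAGGCCTTGGTAGAACCTTTGCNGTATAAGGAGCTGGCGTGCGGGCATACTCCC
GTTCTGCTACCATACTATGGGAACATAAGTCTGTTGCAGGGTCTGGTTTGCGTTCGTTCA
TCACATGAAGCTAACACCTCTTTTCGAGATGCCATGGCATGGAAGGTTTATTTATGCCGG
AACACCGTGTCTCCCCCTAACCCGTCCAAGTCAGTCCAACCTTGACACACAGTGCTCCTA
ACTCGATACCGGGGTCCTTTTGCCGGCCTCGCGGTTCGCCTAAAGTGGATGCCTCAAAAC
CGTCCGTCTTCCAACTTCAGGAGAGTGGCNGTATCCTGTTGGTTGTGAGCCATTCAACCA
AAACCGCCTTTCGGTTGACAGCAGTCGGGGATTGATAGTAGTCGCCACAATTACACTACC
GCTCTGTGTAGCGTCGTCCAGATCTCTTTCGGACTCCAACTAAAACTCGTGGGTCGATGG
CTGTCGCAATTTGTGACTCATCAAGTTTGCAAAGCAACTGCCCTGAATTGAGAGGGCCAT
AAAGCCGTCTCCCTCGTAGACTGTCTGTNTTGGCGGGTTTGCTGGTACCTTCTAATGTAT
AAGGAAGATGAGGGTATCCCTAGGGCCGGTACTTTGACAATAACGCTCTGCCCTAATA
>SIM0012
AGGATCCAGGCCTTGGTAGAACCTTTGCTGTATAAGGAGCTGGCGTGCGGGCATACTCCC
GTTCTGCTACCATACTATGGGAACATAAGTCTGTTGCAGGGTCTGGTTTGCGTTCGATCA
TGACATGAAGCTAACACCTCGTTTCGAGATGCCATGGCATGGAAGGTTTATTTATGCCGG
AACACCGTGTCTCCCCCTAACCCGTCCAAGTCAGTCCAACCTTGACACACAGTGCTCCTA
ACTCGATACCGGGGTCCTTTTGCCGGNCTAGCGGTTCGCCTAAAGTGGATGCCTCAAAAC
CGTCCGTCTTCCAACTTCAGGAGAGNGGCCGTATCCTGTTGGATGTGAGCCATTCAACCA
AAACCGCCTTCCGGTTGACAGCAGTCGGGGATTGATAGTAGTCGCCACAATTACACTACC
GCTCTGTGTAGCGTCGTCCAGATCTCTTTCGGACTCCAACTAAAACTCGTGGGTCGATGG
CTGTCGCAATTTGTGACTCATCAAGTTTGCAAAGCAACTGCCCTGAATTGAGAGGGCCAT
AAAGCCGTCTCCCTTGTAGACTGTCTGTCTTGGCGGGTTTGCTGGTACCTTCTAATGTAT
AAGGAAGATGAGGGTATCCCTAGGGCCGGNACTTTGACAATAACGCTCTGCCCTAATA
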