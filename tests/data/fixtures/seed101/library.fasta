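>SIM0001
TGCATCGGCCTTTGCATGATTCGACAATTGGNCCCCACCGGACCAACAATTTGGCCTCTC
ATGGTGTGCTCCGTTAGTCACAACCGACGCACAAGACCGTGCTGCCAAAAGTTGATTCAA
GTACTAATTCTAGTGGTTGATGTTTCGTCGCATTTTACTCCGGTGGAGTCGCACGCGCCC
AACTATGATACGAGATCAGAGGTACATGGCCTTAATCAAATACCGAGGTGCGAAGGAGAC
TACTCTGGATCTCAGCATCTTTGACTCGAGTATATCCAGACAGCACCCCGTCTATTGTAT
GATACGATACTACCGTACGATAACGCGTACAACCCAAAGTCGAACTTCTACAGCATTACT
GATTTGAATAACCATGCCAGTCGTCACGGGTTTTACGCCAAATCATTCCTGAATATCTGA
CCACCATGGATAACGTGCTACTGTCCGGATGCTCACCACTTTACTATTGAAGAGACGGTT
TGACCTGAGGTAAAGCGCTATCGGTCTCTTGAACTCACTGGACATAACATAAATAGGAGC
CCTTTATATTGTGCACCTAGGCACACTACGGTTGACTGAACGCTGGTGCCCCACGACTAT
TCTAACTTCGCAAAACATCCCGCGTACCATACGTACGTACCCTGTCAATGCACCGCAT
>SIM0002
TGCATCGGCCTTTACATGATTCGACAATTGGTCCCCACCGGACCAACAATTTGGTCTCTC
ATGGTGTGCTCCGTTAGTCACAACCGACGCACAAGACCGTGCTGCCAAAAGTTGATTCAA
GAACTAACTCTAGTGGTTGATGTTTCGTCGCATTTTACTCCGGTGGAGTCGCACGCACCC
AACTATGATACGAGATCAGAGGTACATGGCCTCAATCAAATACCGAGGTGCGAAGGAGAC
TACTCTGGCTCTCAGCATCTTTGACTCGAGTATATCCAGACAGCACCCTGTCTATTGTAT
GATACGATACTACCGTACGATAACGCGTACAACCCATCGTCGAACTTCTACAGCATTACT
GATTTGAATAACCATGCCAGTCGTCACGAGTTTTACGCCGAATCATTCCTGAATATCTGA
CCACCATGGATAACGTGATACTGTCCGGATGCTCACCACTTTACTATTGAAGAGACGGTT
TGACCTGAGGTAAAGCGCTATCGGTCTCTTGAACTCACTGGACATAACATAAATAGGAGN
CCTTTATATTGTGCACCTAGGCACACTACGGTTGACTGAACGCTGGTGCCCCACGACTAT
TCTAACCTCGCAAAACATTCCGCGTATCATACGTACGTACCCTGTCAATGCACTGCAT
>SIM0003
TGCATCGGCCTTTACATGATTCGACAATTGGTCCCCACAGGACCAACAATTTGGCCTCTC
ATGGTGTGCTCCGTTAGTCACAACCGACGCACAAGACCGTGCTGCCAGAAGTTGATTCAA
GAACTAATTCTAGTGGTTGATGTTTCGTCGCATTTTACTCCGGTGGAGTCGCACGCACCC
AACTATGATACGAGATCAGAGGTACATGGCCTCAATCAAATACCGAGGTGCGAAGGGGAC
TACTCTGGCTCTCAGCATCTTTGACTCGAGTATATCCAGACAGCACCCCGTCTATTGTAT
GATACGATACTACCGTACGATAAGGCGTACAACCCAAAGTCGAACTTCAACAGCATTATT
GATTTGAATAACCATGCCAGTCGTCACGGGTTTTACGCCGAATCATTCCTGAATATCTGA
CCACCATGGATAACGTGCTACTGTCCGGATGCTCACCACTTTACTATTGAAGAGACGGTT
TGACCTGAGGTAAAGCGCTATCGGTCTCTTGAACTCACTGGACATAACATAAATAGGAGC
CCTTTATATTGTGCACCTAGGCACACTACGGTTGACTGAACGCTGGTGCCCCACGACTAT
TCTAACCTCGCAAAACATCCCGCGTATCATACGTACGTACCCTGTCAATGCACNGCAT
>SIM0004
TGCATCGGCCTTTACGTGACTCGGCGATTGGTCCCCGCTGGGCCAACATTTTCGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACACACGAGAACGTGCTGCCTAAAGCTGATTGAA
GAACAAGTTATAGTGTTTGNCGCATCGTCATATTTTACTCCGGTGGAGTCGCACGCACCC
GACTATGGCCCGTGATTAGTGGTACATGGCCTCAATCAAATACCGAGGTGCAAAGGAGCC
TACTCTAGCTCTCAGCATCTTTGACCCGAGTATATCCAGACAGCACCCCGTCAATTGTAT
GATACAATACTACCGTATGACAACG
>SIM0005
TGCATCGGCCTTTACATGATTCGACGATTGATCCCCGACGGACCAACATTTTCGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACACACAAGAACGTGATGCCCAAAGCTGATTGAA
AAAAAAGTTATAGTGACTTACGTTTCGTCATATTTTACTCCGGTGGAGTCGCACGCACCC
GGCTATGGCCCGAGATTAGTGGTACATGGCCTCAATCAAATACCGAGGTGCAAAGGAGAC
TACTCTGGCTCTCAGCATCTTTGACCCGAGTATATCCAGACAACACCCCGTCAATTGTAT
GCTACGATACTACCGTATGACAACGCGTACAACCCAACATCGAACTTCTACAGCTTTACT
GATTTGAATAACCATGCCAGTCGTCACGGATTTTACNCCGAATCACTCCTGAATATCTGA
CCACCATGGAAAACGTGCTACTCTCCGGATGCTCTCCACATTACTATTGTCGAAACGGTT
TGACCTGAGGTAAAGCGCTATCGGTCTCTTGAACTCACTGGACATAACATAGGTAGGAGC
CCTTTATCTTGTGCACCAAGGGACGCTACCGTTGACTGCACGCTGGTGCCCCACGACTGT
TCTAACCTCGCAANACATCCCGCGTATGATACGTACCAACCCTGTCAATGCACTGCAT
>SIM0006
TGCATCGGCTTTTACGTGACTCAGCGATTGGTCCCCGCTGGGCCAACATTTTCGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACACACAAGAACGTGCTGCCTAAAGCTGATTGAA
GAACAAGTTATAGTGTTTGACGCATCGTCATATTTTACTCCGGTGGAGTCGCACGCACCC
GACTATGGCCCGTGATTAGTGGTACGTGGCCTCAATCAAATACCGAGGTGCAAAGGAGCC
TACTCTAGCTCTCAGCATCTTTGACCCGAGTATATCCAGACAGCACCCCGTCAATTGGAT
GATACGATACTACCGTATGACAACG
>SIM0007
TGTATCGGCCTTTACATGATCCGACGATTGGTCCCCGCCGCACCAACATTATGGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACGCACACGAATGTGCCGCCTAAAGCTGGTTCAG
GAAAAAATCACGGTAACTGACGTTCCGTCATATTTTACTCCGGAGGGTTCGCACGCACCC
GACTATGGCCTGAGATTAGTGGTACAAAGTCTCAATCGAATACCGAGACGGGAAGGAGAT
TGCTCTGGCTCTCCGCATCTTTGACTTGAGTATATCCATATAGTACCCCGTCTATTATAT
GATACGACACAACCGTACGACAACGCGTACGACTGAATATCGAACTTCTACAGCATTGCT
GACTCGAATAACCAGGCCAGTCGTCACGAGCCTTACGCCCAATGATTCCTGAACATCTGA
CTACCATGGATAACGTGCTCCTCTCTGGTCGGTCGCCACCTTACTATTGAAGAGGTGGTT
TGACCTGAGGTAAAGCGCTATCGGGCTCTTGAATTCTCTCGACGTAACATAGATATGAGC
CCTTTATCTTGTACAGCTAGGGACACTACGGTCCACTGAACGCCGGTGTCGCACGCCTGT
ACTAAGCTCGCTAAACGTCCCGCCTATCACACGTACCTACTCTGTGCATGCACTCCAT
>SIM0008
TGTATCGGCCTTTACATGATCCGACGATTGGTCCCCGCCGCACCAACATTATGGTCTCTC
ATGGTATACTCAGTTAGTCACAACCGACGCACACGAATGTGCCGCCTAAAGCTGGTTCAG
GAAAAAATCATGGTACCTGACGTTCCGTCATATTTTACTCCGGAGGGTTNGCACGCACCC
GACTATGGCCTGAGATTAGTGGTACAAAGTCTCAATCGAATACCGAGACGCGAAGGAGAT
TGCTCTGGCTCTCTGCATCTTTGACTTGAGTATATCCAGATAGTACCCCGTTTATTATAT
GATACGACGCAACCGTACGACAACGCGTACGACTGAATATNGAACTTCTACGGCATTGTT
GACTCGAATAACCATGCTAGTCGTCACGAGCCTTACGCCCAATGATTCCTGAACATCTGA
CTACCATGGATAACGTGCTCCTCTCTGGTCGGTCGCCACCTTACTATTGAAGAGGTGGCT
TGATCTGAGGTAAAGAGCTATCGGGCACTTGAATTCTCTCGACGTAACATAGCTATGAGC
TCTTTATCTTGTACAGCTAGGGACACTACGGTCCACTGAACCCCGGTGTCGCACGCCTGT
ACTAAGCTCGCTAAACGTCCCGCCTATCACACGTACCTACTCTGTGCATGCACTCCAA
>SIM0009
TGTATCGGCCTTTACATGATCCGACGATTGGTCCCCGCCGCACCAACATTATGGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACGCACACGAATGTGGCGCCTAAAGCTGGTTCAG
GAAAAAATCATGGTAACTGACGTTCCGTCATATTTTACTTCGGAGGGTTCGCACGCACCC
GACTATGGCCTGAGATTAGTGGTACAAAGTCTCAATCGAATACCGAGACGCGAAGAAGAT
TGCTCTGGCTCTCTGCATCTTTGACTTGAGTATATGCAGATAGTACCCCGTTTATTATAT
GATACGACACAACCGTACGACAACGCGTACGACTGAATATCGAACTTCTACAGCATTGCT
GACTCGAATAACCATGCCAGTCGTCACGAGCCTTACGCCCAATGATTCCTGAACATCTGA
CTACCATGGATAACGTGCTCCTCTCTGGTCGGTCGCCACCTTACTATTGAAGAGGTGGTT
TGACCTGAGGTAAAGCGCTATCGGGCTCTTGAATTCTCTCGACGTAACATAGATATGAGC
CCTTTATCTTGTACAGCTAGGGACACTACGGTCCACTGAACGCCGGTGTCGCACGCCTGT
ACTAAGCTCGCCAAACGTCCCGCCTATCACACGTACCTACTCTGTGCATGCACTCCGA
>SIM0010
TGTATCAGCCTTTACATGATCCGTCGATTGATCCCCGCCGCACCAACATTATGGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACACACACGAATGTGCTGCCTAAGGCCGATTCAA
GTACAAATCATGATAACTGACGTTCCGTCATATTTCATTCGGGAGGGGTTACACGCAACC
GACTATGGCCTGAGATTATGGGTACAACGTCTCAATCAAATACCAAGACGCGGAGGAGAT
TGCTCTGGCTTTCAGCATCTTTGACTTAAGGATATCCAGATAGTACCCCGTTTATTGTAT
GATACGACACTACCGTATGACAACGCGTATAACTGAATATCGAACTTCTACTGCATTACT
GACTCGAATAACCATGCCAGTCGTCACGAGCCTTACGCTCAGTGACTCTTGAACATCAGA
CTACCATGTATAACGTGCTCTTTTCCGGATGGTCGCCAACTCACTATCGAAGNGATGATT
TGACCTGAGGTAAAGCGCTATCGGGCTCTTGAATTCTCTTGACGTAACATAGAGAGGAGC
CCTTTATCTTGTACAGCTAGGGACACTACGGTCCACTGAACGCCAGTGCCGCACGCCTGN
ACTAACCTCGCTAAACATCCCGCCTATCGCACGTACCTACCCTGTGCATGTACTCCAA
>SIM0011
TGTATCAGCCTTTACATGATCCGTCGATTGATCCCCGCCGCACCAACATTATGGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACACACACGAATGTGCTGCCTAAGGCTGATTCAA
CTACAAATCATGATAACTGACGTTCCGTCATATTTCATTCGGGAGGGGTTACACGCAACC
GACTATGGCCTGAGATTACGGGTACAACGTCTCAATCAAATACCGAGACGCGAAGGAGAT
TGCTCTGGCTTTCAGCATCTTTGACTTAAGGATATCCAGATAGTACCCCGNTTATTGTAT
GATACGACACTACCGTATGACAACGCGTATAACTGAATATCGAACTTCTACTGCATTACT
GACTCGAATAACCATGCCAGTCGTCACGAGCCTTACGCTCAGTGACTCTTGAACATCAGA
CTACCATGTATAACGTGCTNTTTTCCGGATGGTCGCCACCTCACTATCGAAGAGATGGTT
TGACCTGAGGTAAAGCGCTACCGGGCTCTTGAATTCTCTTGACGTAACATAGAGAGGAGC
ACTTTATCTTGTACAACTAGGGACACTACGGTCCACTGAACGCTAGTGCCGCACGCCTGT
ACTAACCTCGCTAAACATCCCGCCTATCGCACGTACCTACCCTGTGCATGTACTCCAA
>SIM0012
TGTATCAGCCTTTACATGACCCGTCGATTGATCCCCGCCGCACCAACATTATGGCCTCTC
ATGGTATACTCAGTTAGTCACAACCGACACACACGAATGTGCTGCCTAAGGCTGATTCAA
GTACAAATCATGATAACTGACGTTCCGTCATATTTCATTCGGGAGGGGTTACACGCAACC
GACTATGGCCTGAGATTATGGGTACAACGTCTCAATCAAATACCGAGACGCGAAGGAGAT
TGCTCTAGCTTTCAGCATCTTTGACTTAAGGATATCCAGATAGTACCCCGTTTATTGTAT
GATACGACACTACCGTATGACAACGCGTATAACTGAATATCGAACTTCTACTGCATTACT
GACTCGAATAACCATGCCAGTCGTCACGAGCCTTACGCTCAGTGACTCTTGAACATCAGA
CTACCATGTATAACGTGCTCTTTTCCGGATGGTCGCCACCTCACTATCGAAGAGATGGTT
TGACCTGAGGTAAAGCGCTATCGGGCTCTTGAATTCTCTTGACGTAACATAGAGAGGAGC
CCTTTATCTTGTACAGCTAGGGACACTACGGTCCACTGAACGCCAGTGCCGCACGCCTGT
ACTAACCTCGCTAAACATCCCGCCTATCGCACGTACGTACCCTGTGCATGTATTCCAA
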