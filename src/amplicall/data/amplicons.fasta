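>EGFR_ex18_amplicon synthetic
CATGTCTGGCACTGCTTTCCTCAGGTCAGGGATCTGATGCCTTGCCATTCGGCTGATCTGACCGTCCAAAATTCGGCTGATCTGACCGTCAAAGAATCGGCTGATCTGACCGTCTGCCATCTGGGCTCAGGGACCGTCTGCCATTCGGCTGATTCAGGTCAGGGGTGTATAAGGTAAGGTCCCT
>EGFR_ex19_amplicon synthetic
AGCATGTGGCACCATCTCACTCAGGTCAGGTCAGGTCAGGTCTGACCGTCTGCCAAAATGCTGATCTGACCGTCTGCCATTCGGCTGATAAGGAATTAAGAGAAGCAACATCTCCGAAAGCCAACAAGGAAATCCTCGATTCAGGTCAGGTCAGGTCAGGTCTCAGGCCCACCTTTTCTCAT
>EGFR_ex20_amplicon synthetic
AGCCACACTGACGTGCCTCTTCAGGTCAGGTCAGGTCAGGTCACCGTCCCTCATTCGCAAAATCTGACCGTCTGCCATTCGGCTGATACTACCCAGCTGATCACGCAGCTCATGACCTTCTGCCATTCGGCTGATCTGACCGTCTGCCATTCGGACGATCTGACCTCAGGTCAGGTCAGGTCAGGTCATACGGGGAGGGGAGATAAGG
>EGFR_ex21_amplicon synthetic
TGCAGAGCTTCTTCCCATGATCAGGTCAGGTCAGGTCTGACCGTCTGCCATTCGCGCGATCTGACCCAAAATCATTCGGCTGATCTGACCGTCTGCGTGTCGGCTGATCTGACCGTCTGCCATTCGGACTTTGGCCTGGCCTGCCATTCGGCTGATCTGTCAGGTCAGGTCAGGTGCTGTATTGTTTAACACATGC
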