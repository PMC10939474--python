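>control
TAATACGACTCACTATAGGGCACCCCTACATCGCAGCGGTCTTTCGGGCTAACGGGATCATGGGACTCAG
GGGACAGCCTCAAGCAACATGCCCAGTCCTGACCTTCAATAAGGAAGCAAACTGGGAAGGAGGGTGTCAG
GGATAAAGGGGAGTCCTAGTCAAGGTGTCGGATGTCCTAAGACTTATGATCATTTTCTTAGGGTCTAAGG
GCTCGAGGGTCTGCGGGTCGGTTTCCTTCTAGAATTAGTATCTTCTATAGTGTCACCTAAAT
>carrier
TAATACGACTCACTATAGGGCACCCCTACATCGCAGCGGTCTTTCATGCTAACATGATCATATGACTCAA
TGGACAGCCTCAAGCAACATGCCCAGTCCTGACCTTCAATAAGGAAGCAAACTATGAAGGAATGTGTCAA
TGATAAAATGGAGTCCTAGTCAAGGTGTCGGATGTCCTAAGACTTATGATCATTTTCTTAATGTCTAAAT
GCTCGAATGTCTGCATGTCGGTTTCCTTCTAGAATTAGTATCTTCTATAGTGTCACCTAAAT
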