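>TRBC1_2 consensus amplicon, TCR beta constant region exon 1
GGTCTCGGCCACCTTCTGGCAGAACCCCCGCAACCACTTCCGCTGTCAAGTCCAGTTCTA
CGGGCTCTCGGAGAATGACGAGTGGACCCAGGATAGGGCCAAACCCGTCACCCAGATCGT
CAGCGCCGAGGCCTGGGGTAGAGCAGGTGAGTGGGGCCTGGGGAGATGCCTGGAGGAGAT
TAGG
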