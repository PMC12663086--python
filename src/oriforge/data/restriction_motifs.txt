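# Common E. coli type II restriction-modification recognition motifs to
# avoid during constrained generation (IUPAC; length >= 3, <= 5 degenerate
# positions).
GATC
CCWGG
GGTCTC
GAAABCC
GRGCYC
CCGCGG
CTGCAG
CCNGG
GGYRCC
CRARCAG
GAATTC
CCTNAGG
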