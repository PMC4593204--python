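>SNP55C MDM2-P2 promoter 22-mer probe, C allele at position 11 (1-based)
GACGGTGTCCCTTCTATCGCTG
>SNP55T MDM2-P2 promoter 22-mer probe, T allele at position 11 (1-based)
GACGGTGTCCTTTCTATCGCTG
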