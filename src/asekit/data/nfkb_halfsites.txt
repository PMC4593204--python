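# 5' G-rich half-sites (7 bp) of classical NF-kB elements, the half of the
# site contacted by the p50 subunit.  Source elements: Ig kappa enhancer /
# HIV-1 LTR, IFN-beta PRDII, H-2Kb, IL-6, IL-2R alpha, A20, IL-8.
GGGACTT
GGGAAAT
GGGGATT
GGGATTT
GGGAATC
GGGAAAT
GGGAATT
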