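# asekit

Allele-specific expression (ASE) quantification from allelic peak heights,
two-locus population genetics, and allele-differential promoter motif
scanning.

## The problem

When a regulatory SNP (rSNP) in a gene promoter is heterozygous, the two
alleles of the gene can be transcribed at different rates. Capillary
electrophoresis assays (PLACE-SSCP and relatives) read this out as a pair
of fluorescent peak heights per sample — one peak per allele of an exonic
*marker* SNP — measured in both genomic DNA (gDNA) and cDNA from the same
specimen. `asekit` implements the full analysis that turns those peak
heights into per-sample ASE calls, plus the genetic-epidemiology layer that
accompanies such a study (genotype/allele tables, exact tests, haplotype
frequencies, linkage disequilibrium) and a motif-level analysis of *why* an
rSNP allele changes transcription-factor binding. The packaged reference
data come from a study of the *MDM2*-P2 promoter in endometrial cancer
(SNP55/rs2870820 and SNP309/rs2279744, read out at the 3'UTR marker
rs1690916).

## The method

**ASE calling.** For each marker the allele-1/allele-2 height ratio carries
a multiplicative allele-specific signal bias *b*, estimated from
known-ratio standard mixtures in log space:

    b = exp( mean[ log(observed ratio) − log(known mix ratio) ] )

Corrected ratios are `r = raw / b`. A sample is gated heterozygous when its
genomic minor/major peak fraction is ≥ 0.10 (or a genotype table says so);
a corrected genomic ratio beyond 3-fold in either direction marks
mono-allelic amplification and excludes the sample. For the rest, with
ρ = corrected cDNA ratio / corrected gDNA ratio, the sample is ASE-positive
when

    max(ρ, 1/ρ) − 1 > 0.20

— the symmetric form of the "more than 20% difference between alleles"
convention.

**Population genetics.** Fisher's exact test (two-sided, point-probability
rule, full enumeration over the margin class) on 2×2/2×3 genotype and
allele tables; the exact conditional Hardy–Weinberg test; haplotype
frequencies from phased chromosomes or by EM on the 3×3 joint genotype
table (the double heterozygote is the only phase-ambiguous class); and
D, D′ and r² = D²/(p₁q₁p₂q₂) from the haplotype table.

**Motif scanning.** IUPAC consensus and log₂-odds PWM scanning of both
strands, and an allele-differential report classifying every hit that
covers a SNP as gained, lost or shared between the two alleles.

A synthetic-cohort generator (`asekit.simulate`) draws phased genotypes by
random union of gametes from a haplotype frequency table, assigns true
expression ratios and mono-allelic copy imbalances, and emits noisy peak
heights and calibration series — so the whole pipeline is testable against
known ground truth.

## Worked example

```python
from asekit import SimulationConfig, simulate_study, run_pipeline

cfg = SimulationConfig(seed=0)                      # study-like defaults
peaks, truth = simulate_study(cfg)                  # 45 + 45 samples
results = run_pipeline(peaks, cohorts=dict(zip(truth.sample_id, truth.cohort)))
print(results.summary())
```

```
Allele-specific expression calling
==================================================
calibration rs1690916: bias=1.0116 (n=15, residual sd=0.0709)
--------------------------------------------------
cohort        marker        het  excl  eval  ASE+
cancer        rs1690916      29     1    28     5
cancer-free   rs1690916      19     0    19     0
```

The calibration block shows the signal bias fitted from the 15 standard
rows (5 mixture ratios × 3 replicates; the generating bias was 1.0). Of 45
simulated cancer samples, 29 are heterozygous at the read-out marker, one
is excluded for mono-allelic amplification, and 5 of the 28 evaluable are
called ASE-positive — the run's 4 true ASE samples are all among them, e.g.

```
EMCA-11: gDNA 0.84, cDNA 1.61, rho 1.93, imbalance 0.93 -> ase_positive
```

The popgen layer on the packaged cohort data:

```python
from asekit import datasets, TwoLocusHaplotypeModel

loci = datasets.study_loci()
phased = [h for h, c in datasets.cancer_free_haplotype_counts().items() for _ in range(c)]
print(TwoLocusHaplotypeModel.from_phased(phased, loci=(loci["SNP55"], loci["SNP309"])).fit().summary())
```

```
Two-locus haplotype frequencies (direct, 90 chromosomes)
======================================================
SNP55C-SNP309T                 0.178
SNP55C-SNP309G                 0.467
SNP55T-SNP309T                 0.356
SNP55T-SNP309G                 0.000
------------------------------------------------------
D                            -0.1659
D-prime                        1.000
r-squared                      0.483
```

The two promoter SNPs are in moderate LD (r² = 0.483) with the T-G
haplotype absent. The same workflow is available from the shell:
`ase-kit simulate`, `ase-kit call`, `ase-kit popgen`, `ase-kit hwe`,
`ase-kit fisher --table '58,32;56,34'`, `ase-kit ld`, `ase-kit motif-scan`
and `ase-kit reproduce` (which chains the packaged desk-scale analyses into
one report).

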