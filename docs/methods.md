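# Methods

## Observables and model

The raw observable is a pair of fluorescent peak heights `(h1, h2)` per
(sample, marker SNP, analyte) with analyte ∈ {gDNA, cDNA, standard}. The
model behind the pipeline is multiplicative throughout:

    E[h1 / h2] = b · r

where `b` is a marker-specific allele-1 signal excess (dye incorporation,
conformer mobility and labelling efficiency differ between alleles) and
`r` the underlying molar allele ratio — the copy ratio for gDNA, the
transcript ratio for cDNA, the known mixture ratio for standards. Because
everything acts multiplicatively, all estimation happens on log ratios.

### Calibration

`b` is estimated per marker as the geometric mean of observed/known ratios
over the standard series, i.e. the least-squares fit of
`log(observed) = log(b) + log(known)` with a fixed unit slope. The
residual SD of the log residuals is reported as a dispersion diagnostic.
One multiplicative constant is the richest correction the standard-mixture
design identifies; no intensity-dependent (non-linear) correction is
attempted. Default standard series: molar ratios {0.25, 0.5, 1, 2, 4} × 3
replicates. An explicit `bias_override` (e.g. 1.0) substitutes for
standards when an assay is known unbiased.

### Calling

For each gated heterozygote the corrected genomic ratio `g` and corrected
cDNA ratio `c` give the relative expression ratio ρ = c/g; per-sample gDNA
normalisation cancels residual calibration error and sample-specific
amplification asymmetry. Both corrected ratios and ρ are reported. The
call is

* `excluded_monoallelic` if `max(g, 1/g) > mono_tau` (default 3.0) — a
  somatic copy-number imbalance makes ASE unevaluable;
* `ase_positive` if `max(ρ, 1/ρ) − 1 > ase_threshold` (default 0.20,
  strict) — the symmetric operationalisation of "more than 20% difference
  between alleles". The symmetric form makes the verdict invariant under
  swapping which allele is the numerator;
* `ase_negative` otherwise.

The heterozygote gate is `min(h1,h2)/max(h1,h2) ≥ min_minor_fraction`
(default 0.10, inclusive) on genomic peaks; a genotype table, when
supplied, overrides the peak gate (studies typically genotype by
sequencing). Samples with gDNA but no cDNA record are flagged in the
summary, never silently dropped. Human-readable reports round ratios to 2
decimals; machine outputs keep full precision.

### Error rates under the noise model

With independent log-normal noise of coefficient of variation `cv` on each
peak height, `sd(log ρ) = 2·σ` with `σ = sqrt(log(1+cv²))` (four heights
enter ρ). At the defaults (cv = 0.05, threshold 0.20) the analytic
false-positive rate of the symmetric rule is `2Φ(−ln 1.2 / 0.0999) ≈ 6.8%`
and the per-sample detection probability of a 1.5-fold imbalance is ≈ 98.7%.
The recovery tests measure exactly these rates (pooled FPR 6.6% over ten
seeded cohorts of 200 heterozygotes). A practitioner wanting a ≤ 5% FPR at
this noise level must either replicate measurements or raise the threshold;
the package keeps the field's 20% convention as the default rather than
tuning it.

## Population genetics

* **Fisher's exact test** (2×2 and 2×3): two-sided by the
  point-probability (minimum-likelihood) rule — the p-value sums the
  conditional probabilities of all margin-preserving tables whose point
  probability is ≤ the observed one, with a 1e-7 relative tie tolerance.
  This is the dominant two-sided convention and reproduces the published
  comparison tables at two decimals (0.87 / 0.88 / 0.85 / 1.00). A table
  with a zero margin returns p = 1 with a warning.
* **Hardy–Weinberg**: the exact conditional test (enumeration over all
  heterozygote counts compatible with the observed allele counts),
  preferred over chi-square at n = 45; `hwe_chisq` is provided as an
  option. Both cancer-free promoter-SNP genotype tables are consistent
  with equilibrium (p = 0.35 and 0.77).
* **Haplotypes**: direct counting for phased chromosomes; EM for joint
  genotype counts, starting from linkage equilibrium, tolerance 1e-10 on
  the log-likelihood, ≤ 1000 iterations. For two biallelic loci the only
  phase-ambiguous class is the double heterozygote and the likelihood is
  well-behaved; no random restarts are used. The log-likelihood trace is
  returned and is non-decreasing.
* **LD**: `D = f11 − p1·p2`, `D′ = |D|/D_max`, `r² = D²/(p1 q1 p2 q2)`,
  computed from full-precision haplotype frequencies. Note r² from the
  *rounded* three-decimal frequencies printed in reports differs in the
  third decimal (0.486 vs 0.483 for the packaged cancer-free data);
  computing from counts is the convention adopted here and matches the
  published value.
* Report rounding: percentages one decimal (half-up), p-values two
  decimals, frequencies and r² three decimals.

### A note on the packaged cohort data

The packaged 45-sample cancer cohort table transcribes the published
per-sample listing verbatim, including its single-letter homozygote
shorthand. Aggregating it reproduces the published genotype-table margins
for the 3'UTR marker and both promoter SNPs exactly. For the exon-1 marker
(rs937283) the listing aggregates to 18/20/7 (A/A, A/G, G/G) while the
published summary table prints 19/20/6 — a one-sample inconsistency
internal to the source (sample EMCA-6 is listed as G). The fixture is left
verbatim; tests assert the heterozygote count (20), which both agree on.

## Motif analysis

Scanning is strand-aware with 0-based half-open coordinates internally and
1-based closed coordinates in reports; minus-strand hits are mapped to
plus-strand coordinates with the site given on the motif's strand. IUPAC
matching uses base-set intersection (a subject `R` matches a pattern `R`);
PWM scanning scores `Σ log2(p_col(base)/bg(base))` and requires
unambiguous subjects. PWMs are built from aligned site strings with a 0.5
pseudocount per base per column against a uniform background.

The shipped fixtures encode the claim the module exists to check on the
22-mer *MDM2*-P2 promoter probe `GACGGTGTCC[C/T]TTCTATCGCTG`:

* `NFKB_core` (`GGGRNNY`) — the κB 5' core. The C allele creates
  `GGGACAC` on the minus strand, overlapping the SNP; the T allele has no
  match on either strand.
* `NFKB_consensus10` (`GGGRNNYYCC`) — the full 10-bp κB consensus. It
  matches neither allele: the site the SNP creates is a *half-site* match,
  which is exactly why the p50 homodimer (whose subunit contacts the
  G-rich 5' half) is the relevant binder.
* `NFKB_p50_halfsite` — a 7-bp PWM built from the 5' half-sites of
  classical κB elements (Ig κ/HIV-1 LTR, IFN-β PRDII, H-2Kb, IL-6,
  IL-2Rα, A20, IL-8), threshold 4.0 bits. Best window: 5.72 bits on the C
  allele vs 1.82 on T. A full-site 10-bp matrix was deliberately not used:
  it fails to separate the alleles (the T allele's `GTGTCCTTTC` window
  outscores the half-site match on pyrimidine-rich 3' positions), and it
  models the wrong binding mode for a p50 homodimer.
* `SP1_GC_box` (`KRGGCKRRK`) and `SP1_GT_box` (`GGTGTSS`) — Sp1 elements.
  The GT-box core matches `GGTGTCC` at offset 3 on *both* alleles; it lies
  entirely 5' of the SNP, so the Sp1 site is allele-invariant. The GT-box
  is kept at its 7-bp core precisely because its 8-bp extension would end
  on the SNP itself and spuriously make the Sp1 call allele-specific.

Only the relational claims (κB: C-only; Sp1: both alleles) are asserted;
the exact matrices used by the original black-box promoter-analysis tool
are not recoverable, and no claim is made about which strand that tool
reported.

## Synthetic cohorts

The generator emulates the study design, not the instrument: phased
multi-locus genotypes by random union of gametes (hence Hardy–Weinberg
structure), a point-mass expression model (a fraction `ase_prevalence` of
cancer samples heterozygous at the functional promoter SNP get ratio
`ase_magnitude`, oriented so the suppressed allele — C by default — is the
weaker one; everything else is 1.0), mono-allelic amplification as a gDNA
copy ratio (default 4:1, random orientation) in a `monoallelic_fraction`
of cancer samples, and independent unit-mean log-normal noise per peak
height. Defaults mirror the study conditions: 45 samples per cohort, the
cancer-free promoter haplotype counts 16/42/32/0 with the read-out marker
appended in linkage equilibrium at its observed allele frequency (the real
marker–promoter phase is unreported), prevalence 2/17, mono-allelic
fraction 3/45, cv 0.05, magnitude 1.5.

What it does **not** model: electrophoresis traces or SSCP conformers,
sequence reads, PCR saturation, between-run batch effects, correlated
noise between gDNA and cDNA of one sample, or continuous ASE-magnitude
distributions. Passing recovery tests therefore demonstrate correctness of
the estimation logic under the stated noise model, not robustness to every
laboratory artefact.

Reproducibility: one root seed; stage k draws from
`np.random.SeedSequence(seed, spawn_key=(k,))` (0 = haplotypes,
1 = expression, 2 = peaks, 3 = standards), so identical configurations
give byte-identical output tables and single stages can be regenerated.

## Numerical choices and degenerate inputs

Log-space throughout for ratio estimation; log-gamma sums for enumeration
tests with a cached log-factorial table; haplotype tables validated to sum
to 1 within 1e-9 with offending entries named; monomorphic loci give
p = 1 (HWE) or undefined D′/r² with a warning (LD); empty cohorts, empty
standard lists and zero peak-height pairs are rejected with messages
naming the offending record. EM on an all-zero table is rejected.

## Known limitations

* One multiplicative bias per marker; intensity-dependent distortions are
  out of scope of the calibration design.
* The mono-allelic exclusion bound (3.0) is a pragmatic default; the
  source analyses state the exclusion but no numeric criterion.
* Exact enumeration of 2×c tables is practical for the candidate-SNP
  scale (two rows, n of order hundreds), not for genome-scale tables.
* Two loci only for haplotype EM; no >2-locus phasing.
* At the default noise level the 20% threshold's false-positive rate is
  ≈ 6.8% (see above); single-replicate designs cannot do better without
  raising the threshold.
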