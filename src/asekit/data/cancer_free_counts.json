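{
  "description": "Cancer-free endometrium cohort (n=45): genotype counts per locus in allele1-homozygote / heterozygote / allele2-homozygote order, and two-locus promoter haplotype chromosome counts.",
  "loci": {
    "SNP55": {
      "rsid": "rs2870820",
      "alleles": [
        "C",
        "T"
      ],
      "role": "functional",
      "counts": [
        17,
        24,
        4
      ]
    },
    "SNP309": {
      "rsid": "rs2279744",
      "alleles": [
        "T",
        "G"
      ],
      "role": "functional",
      "counts": [
        12,
        24,
        9
      ]
    },
    "rs1690916": {
      "rsid": "rs1690916",
      "alleles": [
        "G",
        "A"
      ],
      "role": "marker",
      "counts": [
        18,
        23,
        4
      ]
    },
    "rs937283": {
      "rsid": "rs937283",
      "alleles": [
        "A",
        "G"
      ],
      "role": "marker",
      "counts": [
        18,
        23,
        4
      ]
    }
  },
  "promoter_haplotype_counts": {
    "C-T": 16,
    "C-G": 42,
    "T-T": 32,
    "T-G": 0
  },
  "n_chromosomes": 90
}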