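"""Packaged reference data for the MDM2 promoter ASE analysis.

Ships the in-report data the desk-scale analyses run on: the transcribed
endometrial-cancer (EMCA) cohort genotype table (45 samples, four SNP
columns, homozygotes in single-letter shorthand as published), the
cancer-free cohort genotype and promoter-haplotype counts, the 22-mer
MDM2-P2 promoter probe spanning SNP55, and the default transcription-factor
motif fixtures (NF-kB and Sp1).
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd
from Bio import SeqIO

from .loci import LocusDefinition
from .motif import Motif, load_motifs_json
from .popgen import GenotypeCounts

__all__ = [
    "MONOALLELIC_SAMPLES",
    "SNP55_VARIANT_POS",
    "data_path",
    "emca_cohort",
    "cancer_free_genotype_counts",
    "cancer_free_haplotype_counts",
    "study_loci",
    "snp55_probes",
    "snp55_template",
    "default_motifs",
    "nfkb_halfsites",
]

#: EMCA samples with somatic mono-allelic amplification, excluded from ASE
#: evaluation in the source study.
MONOALLELIC_SAMPLES: Tuple[str, ...] = ("EMCA-19", "EMCA-27", "EMCA-34")

#: 0-based position of SNP55 within the 22-mer promoter probe.
SNP55_VARIANT_POS = 10


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("asekit.data") / name


def emca_cohort(normalize: bool = False) -> pd.DataFrame:
    """The 45-sample EMCA cohort genotype table.

    With ``normalize=True`` the published single-letter homozygote
    shorthand is expanded to ``"X/X"`` via :func:`asekit.reporting.parse_cohort_table`.
    """
    if normalize:
        from .reporting import parse_cohort_table

        return parse_cohort_table(data_path("emca_cohort.tsv"), loci=study_loci())
    return pd.read_csv(data_path("emca_cohort.tsv"), sep="\t", dtype=str)


def _counts_blob() -> dict:
    with open(data_path("cancer_free_counts.json")) as fh:
        return json.load(fh)


def study_loci() -> Dict[str, LocusDefinition]:
    """Locus definitions with the study's allele orientations."""
    blob = _counts_blob()
    return {
        name: LocusDefinition(name, tuple(entry["alleles"]), entry["role"])
        for name, entry in blob["loci"].items()
    }


def cancer_free_genotype_counts() -> Dict[str, GenotypeCounts]:
    """Genotype counts per locus for the cancer-free cohort (n = 45)."""
    blob = _counts_blob()
    loci = study_loci()
    return {
        name: GenotypeCounts(loci[name], *entry["counts"])
        for name, entry in blob["loci"].items()
    }


def cancer_free_haplotype_counts() -> Dict[Tuple[str, str], int]:
    """SNP55-SNP309 haplotype chromosome counts (90 cancer-free chromosomes)."""
    blob = _counts_blob()
    return {
        tuple(k.split("-")): v for k, v in blob["promoter_haplotype_counts"].items()
    }


def snp55_probes() -> Dict[str, str]:
    """The two allele-substituted 22-mer promoter probes, keyed 'C' and 'T'."""
    probes = {}
    with open(data_path("probe_snp55.fasta")) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            probes[rec.id[-1]] = str(rec.seq).upper()
    return probes


def snp55_template() -> Tuple[str, int, str, str]:
    """(template sequence, variant position, allele A, allele B) for SNP55."""
    return snp55_probes()["C"], SNP55_VARIANT_POS, "C", "T"


def default_motifs() -> List[Motif]:
    """The shipped NF-kB / Sp1 motif fixtures."""
    with open(data_path("motifs_default.json")) as fh:
        return load_motifs_json(fh)


def nfkb_halfsites() -> List[str]:
    """Classical NF-kB element 5' half-sites used to build the p50 PWM."""
    sites = []
    with open(data_path("nfkb_halfsites.txt")) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                sites.append(line)
    return sites
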