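"""Synthetic cohorts for allele-specific-expression (ASE) studies.

Generates what the laboratory workflow would observe: phased multi-locus
genotypes drawn by random union of gametes from a haplotype frequency table,
a true per-sample allelic expression ratio (1.0 unless the sample carries an
expression imbalance at a functional promoter SNP), fluorescent peak-height
pairs for gDNA and cDNA at each heterozygous marker SNP, and known-ratio
standard mixture series used downstream for calibration.

Noise model: every emitted peak height is multiplied by an independent
log-normal factor with unit mean and the configured coefficient of
variation.  Allele-specific signal bias (dye or conformer effects that make
one allele's peak systematically higher) is a per-marker multiplicative
factor on the allele-1 height.

Reproducibility: one root seed; each stage draws from a child generator
derived as ``np.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed
stage counter ``k`` (0 = haplotype sampling, 1 = expression model,
2 = peak emission, 3 = standard series), so stages can be regenerated
independently and whole runs are byte-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .loci import HaplotypeFrequencyTable, LocusDefinition

__all__ = [
    "CohortSample",
    "SimulationConfig",
    "default_study_table",
    "sample_haplotype_pairs",
    "assign_expression_model",
    "emit_peak_signals",
    "emit_standard_series",
    "simulate_study",
    "truth_table",
    "write_peak_tsv",
    "write_truth_tsv",
]

_STAGE_HAPLOTYPES = 0
_STAGE_EXPRESSION = 1
_STAGE_PEAKS = 2
_STAGE_STANDARDS = 3

#: base total fluorescence per (sample, analyte); arbitrary units.  Every
#: downstream statistic is a ratio, so the value is immaterial (scale-free).
_BASE_HEIGHT = 1000.0

PEAK_COLUMNS = [
    "sample_id",
    "locus_id",
    "analyte",
    "known_ratio",
    "height_allele1",
    "height_allele2",
]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class CohortSample:
    """One simulated individual with phased haplotypes and ground truth."""

    sample_id: str
    cohort: str  # "cancer-free" or "cancer"
    haplotype_pair: Tuple[Tuple[str, ...], Tuple[str, ...]]
    true_expression_ratio: float = 1.0
    ase_truth: bool = False
    monoallelic_truth: bool = False
    # gDNA copy ratio of haplotype 1 over haplotype 2 (1.0 unless the sample
    # carries a somatic mono-allelic amplification)
    copy_ratio: float = 1.0

    def genotype(self, locus_index: int) -> Tuple[str, str]:
        return (
            self.haplotype_pair[0][locus_index],
            self.haplotype_pair[1][locus_index],
        )

    def is_heterozygous(self, locus_index: int) -> bool:
        a, b = self.genotype(locus_index)
        return a != b


def default_study_table() -> HaplotypeFrequencyTable:
    """Three-locus haplotype table emulating the endometrial study population.

    The two MDM2-P2 promoter SNPs (SNP55 C/T functional, SNP309 T/G) use the
    cancer-free two-locus haplotype counts 16/42/32/0 of 90 chromosomes
    (55C-309T, 55C-309G, 55T-309T, 55T-309G).  The 3'UTR read-out marker
    rs1690916 (G/A) is appended in linkage equilibrium with the promoter
    haplotypes at its cancer-free allele frequency (G = 59/90); the real
    marker-promoter phase is unreported, so independence is the neutral
    choice.
    """
    snp55 = LocusDefinition("SNP55", ("C", "T"), role="functional")
    snp309 = LocusDefinition("SNP309", ("T", "G"), role="functional")
    marker = LocusDefinition("rs1690916", ("G", "A"), role="marker")
    promoter = {("C", "T"): 16.0, ("C", "G"): 42.0, ("T", "T"): 32.0, ("T", "G"): 0.0}
    p_g = 59.0 / 90.0
    entries: Dict[Tuple[str, ...], float] = {}
    for (a55, a309), count in promoter.items():
        entries[(a55, a309, "G")] = count / 90.0 * p_g
        entries[(a55, a309, "A")] = count / 90.0 * (1.0 - p_g)
    return HaplotypeFrequencyTable([snp55, snp309, marker], entries).validate()


@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    Defaults emulate the endometrial-cancer study conditions: 45 samples per
    cohort; ASE prevalence 2/17 among evaluable cancer heterozygotes;
    mono-allelic amplification in 3/45 cancer samples with a 4:1 genomic
    copy imbalance; expression imbalance magnitude 1.5 (a 50% difference,
    comfortably beyond the 20% calling threshold); multiplicative peak noise
    with CV 5%; allele-specific signal bias 1.0 at rs1690916.
    """

    n_per_cohort: int = 45
    haplotype_table: HaplotypeFrequencyTable = field(default_factory=default_study_table)
    ase_prevalence: float = 2.0 / 17.0
    ase_magnitude: float = 1.5
    bias_per_marker: Dict[str, float] = field(default_factory=lambda: {"rs1690916": 1.0})
    noise_cv: float = 0.05
    monoallelic_fraction: float = 3.0 / 45.0
    mono_copy_ratio: float = 4.0
    suppressed_allele: str = "C"  # functional-locus allele with lower output
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "SimulationConfig":
        if not 0.0 <= self.ase_prevalence <= 1.0:
            raise ValueError(f"ase_prevalence must be in [0, 1], got {self.ase_prevalence}")
        if not 0.0 <= self.monoallelic_fraction <= 1.0:
            raise ValueError(
                f"monoallelic_fraction must be in [0, 1], got {self.monoallelic_fraction}"
            )
        if not self.noise_cv >= 0.0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not self.ase_magnitude > 0.0:
            raise ValueError(f"ase_magnitude must be > 0, got {self.ase_magnitude}")
        if not self.mono_copy_ratio > 0.0:
            raise ValueError(f"mono_copy_ratio must be > 0, got {self.mono_copy_ratio}")
        self.haplotype_table.validate()
        return self

    def to_json(self) -> str:
        d = asdict(self)
        d["haplotype_table"] = {
            "loci": [
                {"locus_id": l.locus_id, "alleles": list(l.alleles), "role": l.role}
                for l in self.haplotype_table.loci
            ],
            "entries": {
                "-".join(h): f for h, f in sorted(self.haplotype_table.entries.items())
            },
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        tbl = d.pop("haplotype_table")
        loci = [
            LocusDefinition(l["locus_id"], tuple(l["alleles"]), l["role"])
            for l in tbl["loci"]
        ]
        entries = {tuple(h.split("-")): f for h, f in tbl["entries"].items()}
        table = HaplotypeFrequencyTable(loci, entries).validate()
        return cls(haplotype_table=table, **d).validate()


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def sample_haplotype_pairs(
    table: HaplotypeFrequencyTable,
    n: int,
    seed: int,
    cohort: str = "cancer",
    id_prefix: str = "S",
) -> List[CohortSample]:
    """Draw ``n`` phased samples by random union of gametes.

    Each individual's two haplotypes are drawn independently from ``table``,
    the generative assumption behind Hardy-Weinberg proportions.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    table.validate()
    haps = sorted(table.entries)
    probs = np.array([table.entries[h] for h in haps], dtype=float)
    probs = probs / probs.sum()  # exact renormalisation within validation tolerance
    rng = _stage_rng(seed, _STAGE_HAPLOTYPES)
    idx = rng.choice(len(haps), size=(n, 2), p=probs)
    width = max(1, len(str(n)))
    return [
        CohortSample(
            sample_id=f"{id_prefix}{i + 1:0{width}d}",
            cohort=cohort,
            haplotype_pair=(haps[idx[i, 0]], haps[idx[i, 1]]),
        )
        for i in range(n)
    ]


def _functional_index(table: HaplotypeFrequencyTable) -> int:
    # the first functional (promoter) locus in table order drives expression
    for i, locus in enumerate(table.loci):
        if locus.role == "functional":
            return i
    raise ValueError("haplotype table has no functional locus")


def _readout_marker_indices(table: HaplotypeFrequencyTable) -> List[int]:
    return [i for i, l in enumerate(table.loci) if l.role == "marker"]


def assign_expression_model(
    cohort: Sequence[CohortSample],
    config: SimulationConfig,
) -> List[CohortSample]:
    """Fill ``true_expression_ratio``, ``ase_truth`` and ``monoallelic_truth``.

    A fraction ``ase_prevalence`` of *cancer* samples heterozygous at the
    functional locus receive an expression imbalance of ``ase_magnitude``,
    oriented so the haplotype carrying the suppressed allele is the weaker
    one.  All other samples keep ratio 1.0.  A fraction
    ``monoallelic_fraction`` of cancer samples additionally receive a gDNA
    copy imbalance (``mono_copy_ratio``, random orientation).  ``ase_truth``
    is only set for samples heterozygous at at least one read-out marker --
    a homozygous read-out cannot express the imbalance as an observable.
    """
    config.validate()
    table = config.haplotype_table
    f_idx = _functional_index(table)
    marker_idx = _readout_marker_indices(table)
    if config.suppressed_allele not in table.loci[f_idx].alleles:
        raise ValueError(
            f"suppressed allele {config.suppressed_allele!r} is not an allele of "
            f"the functional locus {table.loci[f_idx].locus_id!r}"
        )
    rng = _stage_rng(config.seed, _STAGE_EXPRESSION)
    out: List[CohortSample] = []
    for sample in cohort:
        s = CohortSample(**asdict(sample))
        s.haplotype_pair = tuple(tuple(h) for h in s.haplotype_pair)
        s.true_expression_ratio = 1.0
        s.ase_truth = False
        s.monoallelic_truth = False
        s.copy_ratio = 1.0
        is_cancer = s.cohort == "cancer"
        ase_draw = rng.random()
        mono_draw = rng.random()
        mono_orient = rng.random()
        if is_cancer and s.is_heterozygous(f_idx) and ase_draw < config.ase_prevalence:
            hap1_allele = s.haplotype_pair[0][f_idx]
            if hap1_allele == config.suppressed_allele:
                s.true_expression_ratio = 1.0 / config.ase_magnitude
            else:
                s.true_expression_ratio = config.ase_magnitude
            s.ase_truth = any(s.is_heterozygous(i) for i in marker_idx)
        if is_cancer and mono_draw < config.monoallelic_fraction:
            s.monoallelic_truth = True
            s.copy_ratio = (
                config.mono_copy_ratio if mono_orient < 0.5 else 1.0 / config.mono_copy_ratio
            )
        out.append(s)
    return out


def emit_peak_signals(
    cohort: Sequence[CohortSample],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Emit gDNA and cDNA peak-height rows for every sample at every marker.

    For a heterozygote the expected allele-1/allele-2 height ratio is
    ``bias * copy_ratio`` in gDNA and ``bias * expression_ratio`` in cDNA
    (expression ratio oriented by the phase of the marker alleles);
    homozygotes emit zero height for the absent allele.  Every height is
    multiplied by independent log-normal noise with CV ``noise_cv``.
    """
    config.validate()
    table = config.haplotype_table
    marker_idx = _readout_marker_indices(table)
    for i in marker_idx:
        if table.loci[i].locus_id not in config.bias_per_marker:
            raise ValueError(
                f"no signal-bias entry for marker {table.loci[i].locus_id!r}; "
                "add it to bias_per_marker (1.0 for no bias)"
            )
    rng = _stage_rng(config.seed, _STAGE_PEAKS)
    rows = []
    for s in cohort:
        for i in marker_idx:
            locus = table.loci[i]
            bias = config.bias_per_marker[locus.locus_id]
            a1, a2 = s.genotype(i)
            for analyte in ("gDNA", "cDNA"):
                noise = _lognormal_noise(rng, config.noise_cv, 2)
                if a1 == a2:  # homozygote: single peak
                    h1 = _BASE_HEIGHT if a1 == locus.allele1 else 0.0
                    h2 = _BASE_HEIGHT if a1 == locus.allele2 else 0.0
                    h1 *= noise[0] * (bias if h1 > 0 else 1.0)
                    h2 *= noise[1]
                else:
                    if analyte == "gDNA":
                        ratio = s.copy_ratio  # hap1 : hap2 copy ratio
                    else:
                        ratio = s.true_expression_ratio
                    # orient hap1:hap2 ratio onto allele1:allele2 of this marker
                    if s.haplotype_pair[0][i] != locus.allele1:
                        ratio = 1.0 / ratio
                    h1 = _BASE_HEIGHT * ratio / (1.0 + ratio) * bias * noise[0]
                    h2 = _BASE_HEIGHT / (1.0 + ratio) * noise[1]
                rows.append(
                    (s.sample_id, locus.locus_id, analyte, np.nan, h1, h2)
                )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def emit_standard_series(
    locus: LocusDefinition,
    mix_ratios: Sequence[float],
    config: SimulationConfig,
    replicates: int = 3,
) -> pd.DataFrame:
    """Known-ratio two-allele mixture standards for calibration.

    One row per replicate per molar ratio, with expected observed
    allele-1/allele-2 height ratio = bias * molar ratio and the configured
    multiplicative noise.  Mirrors the in-vitro-transcribed RNA mixtures
    used to calibrate allele quantification.
    """
    config.validate()
    if len(mix_ratios) == 0:
        raise ValueError("mix_ratios must not be empty")
    if any(not r > 0 for r in mix_ratios):
        raise ValueError(f"all mix ratios must be > 0, got {list(mix_ratios)}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    bias = config.bias_per_marker.get(locus.locus_id)
    if bias is None:
        raise ValueError(f"no signal-bias entry for marker {locus.locus_id!r}")
    rng = _stage_rng(config.seed, _STAGE_STANDARDS)
    rows = []
    for ratio in mix_ratios:
        for rep in range(1, replicates + 1):
            noise = _lognormal_noise(rng, config.noise_cv, 2)
            h1 = _BASE_HEIGHT * ratio / (1.0 + ratio) * bias * noise[0]
            h2 = _BASE_HEIGHT / (1.0 + ratio) * noise[1]
            rows.append(
                (
                    f"std-{locus.locus_id}-{ratio:g}-r{rep}",
                    locus.locus_id,
                    "standard",
                    float(ratio),
                    h1,
                    h2,
                )
            )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


DEFAULT_STANDARD_RATIOS = (0.25, 0.5, 1.0, 2.0, 4.0)


def simulate_study(
    config: Optional[SimulationConfig] = None,
    standard_ratios: Sequence[float] = DEFAULT_STANDARD_RATIOS,
    standard_replicates: int = 3,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator: two cohorts, expression model, peaks, standards.

    Returns ``(peaks, truth)`` where ``peaks`` holds gDNA/cDNA rows for both
    cohorts plus standard-series rows for every marker, and ``truth`` is the
    per-sample ground-truth sidecar.
    """
    config = (config or SimulationConfig()).validate()
    table = config.haplotype_table
    free = sample_haplotype_pairs(
        table, config.n_per_cohort, config.seed, cohort="cancer-free", id_prefix="NRM-"
    )
    cancer = sample_haplotype_pairs(
        table, config.n_per_cohort, config.seed + 1, cohort="cancer", id_prefix="EMCA-"
    )
    cohort = assign_expression_model(list(free) + list(cancer), config)
    peaks = emit_peak_signals(cohort, config)
    standards = [
        emit_standard_series(table.loci[i], standard_ratios, config, standard_replicates)
        for i in _readout_marker_indices(table)
    ]
    peaks = pd.concat([peaks] + standards, ignore_index=True)
    return peaks, truth_table(cohort)


def truth_table(cohort: Sequence[CohortSample]) -> pd.DataFrame:
    rows = [
        (
            s.sample_id,
            s.cohort,
            "|".join("-".join(h) for h in s.haplotype_pair),
            s.true_expression_ratio,
            s.ase_truth,
            s.monoallelic_truth,
        )
        for s in cohort
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cohort",
            "haplotypes",
            "true_expression_ratio",
            "ase_truth",
            "monoallelic_truth",
        ],
    )


def write_peak_tsv(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")
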