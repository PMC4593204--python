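"""Locus and haplotype-frequency containers shared by the simulator and the statistics layer.

A :class:`LocusDefinition` fixes the allele orientation for a biallelic SNP:
``alleles[0]`` is the numerator of every allelic ratio reported for that
locus, and the "allele 1" of genotype counts.  A
:class:`HaplotypeFrequencyTable` holds multi-locus gamete frequencies; for
two loci it is the input to the linkage-disequilibrium statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

__all__ = ["LocusDefinition", "HaplotypeFrequencyTable", "VALID_BASES"]

VALID_BASES = frozenset("ACGT")

#: absolute tolerance on the sum of haplotype frequencies
_FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class LocusDefinition:
    """A biallelic locus with a fixed allele orientation.

    Parameters
    ----------
    locus_id : str
        Short label, e.g. ``"SNP55"`` or ``"rs1690916"``.
    alleles : tuple of str
        Ordered pair of single bases; the first allele is the numerator of
        every ratio for this locus.
    role : {"functional", "marker"}
        Whether the locus drives expression differences (a promoter rSNP)
        or merely distinguishes the two transcripts (an exonic marker).
    """

    locus_id: str
    alleles: Tuple[str, str]
    role: str = "marker"

    def __post_init__(self) -> None:
        a1, a2 = self.alleles
        if a1 not in VALID_BASES or a2 not in VALID_BASES:
            raise ValueError(
                f"locus {self.locus_id!r}: alleles must be single bases from "
                f"A/C/G/T, got {self.alleles!r}"
            )
        if a1 == a2:
            raise ValueError(f"locus {self.locus_id!r}: alleles must be distinct")
        if self.role not in ("functional", "marker"):
            raise ValueError(
                f"locus {self.locus_id!r}: role must be 'functional' or 'marker'"
            )

    @property
    def allele1(self) -> str:
        return self.alleles[0]

    @property
    def allele2(self) -> str:
        return self.alleles[1]

    def genotype_index(self, genotype: str) -> int:
        """Map a genotype string like ``"C/T"`` to 0/1/2 copies of allele 2.

        Returns 0 for the allele-1 homozygote, 1 for the heterozygote and
        2 for the allele-2 homozygote.
        """
        alleles = genotype.split("/")
        if len(alleles) == 1:  # homozygote shorthand, e.g. "C" for "C/C"
            alleles = alleles * 2
        if len(alleles) != 2 or any(a not in self.alleles for a in alleles):
            raise ValueError(
                f"genotype {genotype!r} is not over alleles {self.alleles} "
                f"of locus {self.locus_id!r}"
            )
        return sum(a == self.allele2 for a in alleles)


@dataclass
class HaplotypeFrequencyTable:
    """Gamete (haplotype) frequencies over an ordered list of loci.

    ``entries`` maps allele tuples -- one allele per locus, in locus order --
    to non-negative frequencies summing to one.
    """

    loci: Sequence[LocusDefinition]
    entries: Dict[Tuple[str, ...], float] = field(default_factory=dict)

    def validate(self) -> "HaplotypeFrequencyTable":
        n_loci = len(self.loci)
        if n_loci == 0:
            raise ValueError("haplotype table needs at least one locus")
        total = 0.0
        for hap, freq in self.entries.items():
            if len(hap) != n_loci:
                raise ValueError(
                    f"haplotype {hap!r} has {len(hap)} alleles for {n_loci} loci"
                )
            for allele, locus in zip(hap, self.loci):
                if allele not in locus.alleles:
                    raise ValueError(
                        f"haplotype {hap!r}: allele {allele!r} is not an allele "
                        f"of locus {locus.locus_id!r}"
                    )
            if not freq >= 0.0:
                raise ValueError(f"haplotype {hap!r} has negative frequency {freq!r}")
            total += freq
        if abs(total - 1.0) > _FREQ_SUM_TOL:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")
        return self

    @classmethod
    def from_counts(
        cls,
        loci: Sequence[LocusDefinition],
        counts: Dict[Tuple[str, ...], float],
    ) -> "HaplotypeFrequencyTable":
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError("haplotype counts are all zero")
        table = cls(loci=list(loci), entries={h: c / total for h, c in counts.items()})
        return table.validate()

    def allele_frequency(self, locus_id: str, allele: str) -> float:
        """Marginal frequency of ``allele`` at the named locus."""
        idx = [l.locus_id for l in self.loci].index(locus_id)
        return sum(f for hap, f in self.entries.items() if hap[idx] == allele)

    def haplotypes(self) -> list:
        return sorted(self.entries)

    def frequency(self, hap: Tuple[str, ...]) -> float:
        return self.entries.get(tuple(hap), 0.0)
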