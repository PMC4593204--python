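"""Two-locus population genetics: frequency tables, exact tests, haplotypes, LD.

Covers the genetic-epidemiology layer of a candidate-SNP case/control
study: genotype and allele frequency tables with report-style rounding,
Fisher's exact test on 2x2 / 2x3 contingency tables (two-sided by the
point-probability rule, computed by full enumeration over the margin
class), the exact conditional Hardy-Weinberg test, haplotype frequency
estimation from phased chromosomes or by EM from joint genotype counts
(the double heterozygote being the only phase-ambiguous class for two
biallelic loci), and the linkage-disequilibrium coefficients D, D' and r2.

:class:`TwoLocusHaplotypeModel` wraps haplotype estimation as a
model/results pair; the individual statistics are plain functions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .loci import HaplotypeFrequencyTable, LocusDefinition

__all__ = [
    "GenotypeCounts",
    "TestResult",
    "LDStats",
    "round_half_up",
    "genotype_frequency_table",
    "allele_counts_from_genotypes",
    "fisher_exact",
    "hwe_exact",
    "hwe_chisq",
    "haplotype_frequencies_direct",
    "haplotype_frequencies_em",
    "ld_from_haplotypes",
    "haplotypes_from_allele_freqs",
    "TwoLocusHaplotypeModel",
    "TwoLocusHaplotypeResults",
]

#: relative tolerance when comparing point probabilities for two-sided tests
TIE_RTOL = 1e-7


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, the convention of printed reports."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic locus.

    ``n_11`` homozygotes for allele 1, ``n_12`` heterozygotes, ``n_22``
    homozygotes for allele 2, with the allele orientation taken from
    ``locus``.
    """

    locus: LocusDefinition
    n_11: int
    n_12: int
    n_22: int

    def __post_init__(self) -> None:
        if min(self.n_11, self.n_12, self.n_22) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_11 + self.n_12 + self.n_22

    @property
    def allele1_count(self) -> int:
        return 2 * self.n_11 + self.n_12

    @property
    def allele2_count(self) -> int:
        return 2 * self.n_22 + self.n_12

    def as_row(self) -> Tuple[int, int, int]:
        return (self.n_11, self.n_12, self.n_22)


@dataclass(frozen=True)
class TestResult:
    method: str
    p_value: float
    statistic: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage-disequilibrium coefficients.

    ``p1``/``p2`` are the allele-1 frequencies at the two loci, ``D`` the
    disequilibrium coefficient f(A1B1) - p1*p2, ``d_prime`` its normalised
    magnitude and ``r_squared`` the squared allelic correlation.  The
    normalised statistics are ``None`` when a locus is monomorphic.
    """

    p1: float
    p2: float
    D: float
    d_prime: Optional[float]
    r_squared: Optional[float]


def genotype_frequency_table(
    genotypes: Iterable[str],
    locus: LocusDefinition,
) -> Tuple[GenotypeCounts, Optional[Dict[str, float]]]:
    """Count genotypes and report percentages rounded half-up to one decimal.

    Genotype strings are ``"C/T"`` style, or single-base homozygote
    shorthand.  Returns ``(counts, percentages)``; percentages are ``None``
    for an empty input.  A genotype over foreign alleles is rejected naming
    the offending sample index.
    """
    counts = [0, 0, 0]
    for i, g in enumerate(genotypes):
        try:
            counts[locus.genotype_index(g)] += 1
        except ValueError as err:
            raise ValueError(f"sample #{i + 1}: {err}") from None
    gc = GenotypeCounts(locus, *counts)
    if gc.n == 0:
        return gc, None
    labels = [
        f"{locus.allele1}/{locus.allele1}",
        f"{locus.allele1}/{locus.allele2}",
        f"{locus.allele2}/{locus.allele2}",
    ]
    pct = {lab: round_half_up(100.0 * c / gc.n, 1) for lab, c in zip(labels, counts)}
    return gc, pct


def allele_counts_from_genotypes(gc: GenotypeCounts) -> Dict[str, dict]:
    """Chromosome counts and percentages per allele from genotype counts."""
    n_chrom = 2 * gc.n
    out = {}
    for allele, count in (
        (gc.locus.allele1, gc.allele1_count),
        (gc.locus.allele2, gc.allele2_count),
    ):
        out[allele] = {
            "count": count,
            "percent": round_half_up(100.0 * count / n_chrom, 1) if n_chrom else None,
        }
    return out


_LF_CACHE = np.zeros(1)


def _log_factorials(n: int) -> np.ndarray:
    global _LF_CACHE
    if len(_LF_CACHE) <= n:
        m = max(n + 1, 2 * len(_LF_CACHE))
        _LF_CACHE = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, m)))))
    return _LF_CACHE


def fisher_exact(table: Sequence[Sequence[int]], tie_rtol: float = TIE_RTOL) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 or 2x3 table by enumeration.

    Enumerates every table with the observed margins; the p-value is the
    total conditional (multivariate hypergeometric) probability of tables
    whose point probability does not exceed the observed one, with a small
    relative tolerance for floating-point ties.  A table with a zero row or
    column margin carries no information: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if (rows == 0).any() or (cols == 0).any():
        warnings.warn("table has a zero margin; no association is testable")
        return TestResult("fisher_exact", 1.0, note="zero margin")
    lf = _log_factorials(n)
    log_const = lf[rows].sum() + lf[cols].sum() - lf[n]

    def log_prob(first_row: Sequence[int]) -> float:
        cells = list(first_row) + [c - x for c, x in zip(cols, first_row)]
        return log_const - sum(lf[x] for x in cells)

    log_obs = log_prob(t[0])
    log_cut = log_obs + math.log1p(tie_rtol)
    p = 0.0
    r0 = int(rows[0])
    ranges = [range(min(r0, int(c)) + 1) for c in cols[:-1]]
    for partial in itertools.product(*ranges):
        last = r0 - sum(partial)
        if last < 0 or last > cols[-1]:
            continue
        lp = log_prob(list(partial) + [last])
        if lp <= log_cut:
            p += math.exp(lp)
    return TestResult("fisher_exact", min(p, 1.0), statistic=math.exp(log_obs))


def hwe_exact(gc: GenotypeCounts, tie_rtol: float = TIE_RTOL) -> TestResult:
    """Exact conditional Hardy-Weinberg test for a biallelic locus.

    Conditions on the observed allele counts and enumerates every
    compatible heterozygote count (same parity as the minor-allele count);
    p is the total conditional probability of configurations no more
    probable than the observed one.  A monomorphic locus gives p = 1.
    """
    n = gc.n
    n_a = min(gc.allele1_count, gc.allele2_count)
    if n == 0:
        raise ValueError("no genotypes")
    if n_a == 0:
        return TestResult("hwe_exact", 1.0, note="monomorphic locus")
    lf = _log_factorials(2 * n)

    def log_prob(n_het: int) -> float:
        n_rare_hom = (n_a - n_het) // 2
        n_common_hom = n - n_het - n_rare_hom
        # P(n_het | n, n_a) up to the shared normalising constant
        return (
            n_het * math.log(2.0)
            + lf[n]
            - lf[n_het]
            - lf[n_rare_hom]
            - lf[n_common_hom]
        )

    hets = range(n_a % 2, n_a + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    log_norm = _logsumexp(list(logs.values()))
    obs = logs[gc.n_12]
    cut = obs + math.log1p(tie_rtol)
    p = sum(math.exp(lp - log_norm) for lp in logs.values() if lp <= cut)
    return TestResult("hwe_exact", min(p, 1.0), statistic=math.exp(obs - log_norm))


def _logsumexp(values: List[float]) -> float:
    m = max(values)
    return m + math.log(sum(math.exp(v - m) for v in values))


def hwe_chisq(gc: GenotypeCounts) -> TestResult:
    """One-degree-of-freedom chi-square alternative to the exact test."""
    from scipy import stats

    n = gc.n
    if n == 0:
        raise ValueError("no genotypes")
    p1 = gc.allele1_count / (2 * n)
    if p1 in (0.0, 1.0):
        return TestResult("hwe_chisq", 1.0, note="monomorphic locus")
    expected = np.array([n * p1 * p1, 2 * n * p1 * (1 - p1), n * (1 - p1) ** 2])
    observed = np.array(gc.as_row(), dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return TestResult("hwe_chisq", float(stats.chi2.sf(stat, df=1)), statistic=stat)


def haplotype_frequencies_direct(
    haplotypes: Sequence[Tuple[str, ...]],
    loci: Optional[Sequence[LocusDefinition]] = None,
) -> HaplotypeFrequencyTable:
    """Relative frequencies of directly observed (phased) chromosomes."""
    haps = [tuple(h) for h in haplotypes]
    if not haps:
        raise ValueError("no haplotypes given")
    if loci is None:
        loci = _infer_loci(haps)
    counts: Dict[Tuple[str, ...], float] = {}
    for h in haps:
        counts[h] = counts.get(h, 0.0) + 1.0
    # carry explicit zeros for unobserved combinations over the defined alleles
    for combo in itertools.product(*[l.alleles for l in loci]):
        counts.setdefault(combo, 0.0)
    return HaplotypeFrequencyTable.from_counts(loci, counts)


def _infer_loci(haps: Sequence[Tuple[str, ...]]) -> List[LocusDefinition]:
    n_loci = len(haps[0])
    loci = []
    for i in range(n_loci):
        alleles = sorted({h[i] for h in haps})
        if len(alleles) == 1:
            alleles = alleles + [next(b for b in "ACGT" if b != alleles[0])]
        if len(alleles) != 2:
            raise ValueError(f"locus index {i} is not biallelic: {alleles}")
        loci.append(LocusDefinition(f"locus{i + 1}", tuple(alleles)))
    return loci


def haplotype_frequencies_em(
    joint_counts: Sequence[Sequence[int]],
    loci: Optional[Tuple[LocusDefinition, LocusDefinition]] = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> Tuple[HaplotypeFrequencyTable, List[float]]:
    """EM estimate of two-locus haplotype frequencies from a 3x3 genotype table.

    ``joint_counts[i][j]`` is the number of samples with ``i`` copies of
    allele 2 at locus A and ``j`` copies at locus B.  Only the double
    heterozygote has ambiguous phase; EM reallocates it between the
    cis (A1B1/A2B2) and trans (A1B2/A2B1) resolutions.  Starts from
    linkage equilibrium; the log-likelihood trace is returned and is
    non-decreasing.
    """
    j = np.asarray(joint_counts, dtype=float)
    if j.shape != (3, 3) or (j < 0).any():
        raise ValueError("joint_counts must be a non-negative 3x3 matrix")
    n = j.sum()
    if n == 0:
        raise ValueError("all joint genotype counts are zero")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if loci is None:
        loci = (
            LocusDefinition("locusA", ("A", "C")),
            LocusDefinition("locusB", ("A", "C")),
        )
    # chromosome counts of allele 2 at each locus
    n_chrom = 2.0 * n
    q_a = (j[1, :].sum() + 2.0 * j[2, :].sum()) / n_chrom
    q_b = (j[:, 1].sum() + 2.0 * j[:, 2].sum()) / n_chrom
    p_a, p_b = 1.0 - q_a, 1.0 - q_b
    # haplotype order: f11, f12, f21, f22 (allele1/allele2 at locus A x B)
    f = np.array([p_a * p_b, p_a * q_b, q_a * p_b, q_a * q_b], dtype=float)
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    def loglik(f: np.ndarray) -> float:
        f11, f12, f21, f22 = f
        probs = np.array(
            [
                [f11 ** 2, 2 * f11 * f12, f12 ** 2],
                [2 * f11 * f21, 2 * (f11 * f22 + f12 * f21), 2 * f12 * f22],
                [f21 ** 2, 2 * f21 * f22, f22 ** 2],
            ]
        )
        with np.errstate(divide="ignore"):
            lp = np.log(probs)
        mask = j > 0
        return float((j[mask] * lp[mask]).sum())

    trace = [loglik(f)]
    for _ in range(max_iter):
        f11, f12, f21, f22 = f
        cis = f11 * f22
        trans = f12 * f21
        denom = cis + trans
        w = cis / denom if denom > 0 else 0.5  # E-step: cis share of double hets
        dh = j[1, 1]
        # expected chromosome counts per haplotype
        c11 = 2 * j[0, 0] + j[0, 1] + j[1, 0] + w * dh
        c12 = 2 * j[0, 2] + j[0, 1] + j[1, 2] + (1 - w) * dh
        c21 = 2 * j[2, 0] + j[1, 0] + j[2, 1] + (1 - w) * dh
        c22 = 2 * j[2, 2] + j[2, 1] + j[1, 2] + w * dh
        f = np.array([c11, c12, c21, c22]) / n_chrom
        trace.append(loglik(f))
        if trace[-1] - trace[-2] < tol:
            break
    la, lb = loci
    entries = {
        (la.allele1, lb.allele1): f[0],
        (la.allele1, lb.allele2): f[1],
        (la.allele2, lb.allele1): f[2],
        (la.allele2, lb.allele2): f[3],
    }
    return HaplotypeFrequencyTable(list(loci), entries).validate(), trace


def ld_from_haplotypes(table: HaplotypeFrequencyTable) -> LDStats:
    """D, D' and r2 from a two-locus haplotype frequency table.

    ``D = f(A1B1) - p1*p2``; ``D' = |D| / D_max`` with the usual bound
    depending on the sign of D; ``r2 = D^2 / (p1 q1 p2 q2)``.  When either
    locus is monomorphic D' and r2 are undefined and reported as ``None``.
    """
    table.validate()
    if len(table.loci) != 2:
        raise ValueError("LD statistics require exactly two loci")
    la, lb = table.loci
    f11 = table.frequency((la.allele1, lb.allele1))
    p1 = table.allele_frequency(la.locus_id, la.allele1)
    p2 = table.allele_frequency(lb.locus_id, lb.allele1)
    q1, q2 = 1.0 - p1, 1.0 - p2
    d = f11 - p1 * p2
    if min(p1, q1, p2, q2) <= 0.0:
        warnings.warn("monomorphic locus: D' and r2 are undefined")
        return LDStats(p1, p2, d, None, None)
    if d > 0:
        d_max = min(p1 * q2, q1 * p2)
    else:
        d_max = min(p1 * p2, q1 * q2)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p1 * q1 * p2 * q2)
    return LDStats(p1, p2, d, d_prime, r2)


def haplotypes_from_allele_freqs(
    p1: float,
    p2: float,
    absent: Tuple[int, int],
    loci: Optional[Tuple[LocusDefinition, LocusDefinition]] = None,
) -> HaplotypeFrequencyTable:
    """Solve the two-locus haplotype system from allele frequencies plus one
    absent haplotype.

    Four haplotype frequencies have three degrees of freedom; the two
    allele-1 frequencies ``p1``/``p2`` fix two, and declaring one haplotype
    absent (``absent`` is an index pair, 0 = allele 1, 1 = allele 2 at each
    locus) closes the system.  Rejects solutions with a negative frequency.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    margins_a = (p1, 1.0 - p1)
    margins_b = (p2, 1.0 - p2)
    i0, j0 = absent
    if i0 not in (0, 1) or j0 not in (0, 1):
        raise ValueError("absent haplotype must be an index pair over {0, 1}")
    f = np.empty((2, 2))
    f[i0, j0] = 0.0
    f[i0, 1 - j0] = margins_a[i0]
    f[1 - i0, j0] = margins_b[j0]
    f[1 - i0, 1 - j0] = 1.0 - margins_a[i0] - margins_b[j0]
    if (f < -1e-12).any():
        raise ValueError(
            "allele frequencies are inconsistent with the absent haplotype "
            f"(negative solution {f.tolist()})"
        )
    f = np.clip(f, 0.0, None)
    if loci is None:
        loci = (LocusDefinition("locusA", ("A", "C")), LocusDefinition("locusB", ("A", "C")))
    la, lb = loci
    entries = {
        (la.alleles[i], lb.alleles[j]): float(f[i, j]) for i in (0, 1) for j in (0, 1)
    }
    return HaplotypeFrequencyTable(list(loci), entries).validate()


class TwoLocusHaplotypeModel:
    """Haplotype-frequency model for two biallelic loci.

    Construct from phased chromosomes (:meth:`from_phased`) or from a joint
    genotype count matrix (:meth:`from_genotype_counts`); ``fit`` returns a
    :class:`TwoLocusHaplotypeResults` carrying the frequency table, the EM
    log-likelihood trace where applicable, and derived LD statistics.
    """

    def __init__(
        self,
        loci: Tuple[LocusDefinition, LocusDefinition],
        phased: Optional[Sequence[Tuple[str, str]]] = None,
        joint_counts: Optional[Sequence[Sequence[int]]] = None,
    ) -> None:
        if (phased is None) == (joint_counts is None):
            raise ValueError("provide exactly one of phased chromosomes or joint counts")
        self.loci = tuple(loci)
        self.phased = [tuple(h) for h in phased] if phased is not None else None
        self.joint_counts = (
            np.asarray(joint_counts, dtype=int) if joint_counts is not None else None
        )

    @classmethod
    def from_phased(
        cls,
        haplotypes: Sequence[Tuple[str, str]],
        loci: Optional[Tuple[LocusDefinition, LocusDefinition]] = None,
    ) -> "TwoLocusHaplotypeModel":
        haps = [tuple(h) for h in haplotypes]
        if loci is None:
            loci = tuple(_infer_loci(haps))
        return cls(loci, phased=haps)

    @classmethod
    def from_genotype_counts(
        cls,
        joint_counts: Sequence[Sequence[int]],
        loci: Tuple[LocusDefinition, LocusDefinition],
    ) -> "TwoLocusHaplotypeModel":
        return cls(loci, joint_counts=joint_counts)

    @classmethod
    def from_genotypes(
        cls,
        genotypes_a: Sequence[str],
        genotypes_b: Sequence[str],
        loci: Tuple[LocusDefinition, LocusDefinition],
    ) -> "TwoLocusHaplotypeModel":
        """Build the 3x3 joint genotype matrix from per-sample genotype strings."""
        if len(genotypes_a) != len(genotypes_b):
            raise ValueError("genotype lists differ in length")
        j = np.zeros((3, 3), dtype=int)
        la, lb = loci
        for ga, gb in zip(genotypes_a, genotypes_b):
            j[la.genotype_index(ga), lb.genotype_index(gb)] += 1
        return cls(loci, joint_counts=j)

    def fit(self, tol: float = 1e-10, max_iter: int = 1000) -> "TwoLocusHaplotypeResults":
        if self.phased is not None:
            table = haplotype_frequencies_direct(self.phased, list(self.loci))
            return TwoLocusHaplotypeResults(
                model=self,
                frequencies=table,
                method="direct",
                n_chromosomes=len(self.phased),
                loglik_trace=[],
            )
        table, trace = haplotype_frequencies_em(
            self.joint_counts, loci=self.loci, tol=tol, max_iter=max_iter
        )
        return TwoLocusHaplotypeResults(
            model=self,
            frequencies=table,
            method="em",
            n_chromosomes=int(2 * self.joint_counts.sum()),
            loglik_trace=trace,
        )


@dataclass
class TwoLocusHaplotypeResults:
    model: TwoLocusHaplotypeModel
    frequencies: HaplotypeFrequencyTable
    method: str
    n_chromosomes: int
    loglik_trace: List[float] = field(default_factory=list)

    def ld(self) -> LDStats:
        return ld_from_haplotypes(self.frequencies)

    def summary(self) -> str:
        la, lb = self.frequencies.loci
        lines = [
            f"Two-locus haplotype frequencies ({self.method}, "
            f"{self.n_chromosomes} chromosomes)",
            "=" * 54,
        ]
        for hap in [
            (la.allele1, lb.allele1),
            (la.allele1, lb.allele2),
            (la.allele2, lb.allele1),
            (la.allele2, lb.allele2),
        ]:
            label = f"{la.locus_id}{hap[0]}-{lb.locus_id}{hap[1]}"
            lines.append(f"{label:<28}{self.frequencies.frequency(hap):8.3f}")
        stats = self.ld()
        lines.append("-" * 54)
        lines.append(f"{'D':<28}{stats.D:8.4f}")
        if stats.d_prime is not None:
            lines.append(f"{'D-prime':<28}{stats.d_prime:8.3f}")
            lines.append(f"{'r-squared':<28}{stats.r_squared:8.3f}")
        if self.loglik_trace:
            lines.append(
                f"EM iterations: {len(self.loglik_trace) - 1}, "
                f"log-likelihood {self.loglik_trace[-1]:.6f}"
            )
        return "\n".join(lines)
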