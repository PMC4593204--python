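"""Strand-aware motif scanning and allele-differential reporting.

Scans short promoter sequences with transcription-factor binding motifs
given either as IUPAC consensus patterns or as position weight matrices
(PWMs, log2-odds against a background model), and reports which motif hits
are gained or lost when a single regulatory SNP switches alleles.

Matching semantics: a subject base matches an IUPAC pattern base iff their
base sets intersect (so an N in the subject matches anything, and an R
matches an R).  PWM scanning requires unambiguous A/C/G/T subjects.  Minus
strand hits are reported in plus-strand coordinates (0-based, half-open)
with the matched site given on the motif's own strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "SequenceRecord",
    "Motif",
    "MotifHit",
    "AlleleDiffReport",
    "reverse_complement",
    "iupac_scan",
    "pwm_scan",
    "scan",
    "pwm_from_sites",
    "allele_differential_scan",
    "load_motifs_json",
    "motifs_to_json",
]

IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase nucleotide sequence (IUPAC alphabet)."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"sequence {self.seq_id!r} is empty")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"sequence {self.seq_id!r} has invalid symbols {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Motif:
    """An IUPAC consensus pattern or a position weight matrix.

    For ``kind="pwm"``, ``matrix`` is a 4 x L array of per-position base
    probabilities (rows A, C, G, T; columns sum to 1; pseudocount-smoothed
    so no entry is zero), ``background`` the base composition of the null
    model, and ``threshold`` the minimum log2-odds score for a hit.
    """

    motif_id: str
    kind: str
    pattern: Optional[str] = None
    matrix: Optional[np.ndarray] = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "iupac":
            if not self.pattern:
                raise ValueError(f"motif {self.motif_id!r}: empty IUPAC pattern")
            self.pattern = self.pattern.upper()
            bad = set(self.pattern) - set(IUPAC_SETS)
            if bad:
                raise ValueError(
                    f"motif {self.motif_id!r}: invalid IUPAC symbols {sorted(bad)}"
                )
        elif self.kind == "pwm":
            m = np.asarray(self.matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
                raise ValueError(f"motif {self.motif_id!r}: matrix must be 4 x L")
            if (m <= 0).any():
                raise ValueError(
                    f"motif {self.motif_id!r}: matrix entries must be positive "
                    "(apply a pseudocount)"
                )
            if np.abs(m.sum(axis=0) - 1.0).max() > 1e-9:
                raise ValueError(f"motif {self.motif_id!r}: matrix columns must sum to 1")
            self.matrix = m
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"motif {self.motif_id!r}: background must be 4 positive "
                    "frequencies summing to 1"
                )
            self.background = bg
        else:
            raise ValueError(f"motif {self.motif_id!r}: kind must be 'iupac' or 'pwm'")

    def __len__(self) -> int:
        return len(self.pattern) if self.kind == "iupac" else self.matrix.shape[1]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in plus-strand coordinates [start, start+length)."""

    motif_id: str
    seq_id: str
    start: int
    length: int
    strand: str
    site: str
    score: Optional[float] = None

    @property
    def end(self) -> int:
        return self.start + self.length

    def overlaps(self, position: int) -> bool:
        return self.start <= position < self.end

    def key(self) -> tuple:
        """Identity of the hit irrespective of score (used for set algebra)."""
        return (self.motif_id, self.start, self.strand)


def _as_record(seq: Union[str, SequenceRecord], seq_id: str = "seq") -> SequenceRecord:
    if isinstance(seq, SequenceRecord):
        return seq
    return SequenceRecord(seq_id, seq)


def _strand_views(record: SequenceRecord, strands: str):
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    if strands in ("both", "+"):
        yield "+", record.sequence
    if strands in ("both", "-"):
        yield "-", reverse_complement(record.sequence)


def iupac_scan(
    seq: Union[str, SequenceRecord],
    motif: Motif,
    strands: str = "both",
) -> List[MotifHit]:
    """All windows matching an IUPAC consensus on the requested strands.

    Subject ambiguity codes match a pattern base iff their base sets
    intersect.  A pattern longer than the sequence yields no hits.
    """
    if motif.kind != "iupac":
        raise ValueError(f"motif {motif.motif_id!r} is not an IUPAC motif")
    record = _as_record(seq)
    pattern_sets = [IUPAC_SETS[b] for b in motif.pattern]
    L = len(pattern_sets)
    n = len(record)
    hits: List[MotifHit] = []
    for strand, subject in _strand_views(record, strands):
        for i in range(n - L + 1):
            window = subject[i : i + L]
            if all(IUPAC_SETS[b] & p for b, p in zip(window, pattern_sets)):
                start = i if strand == "+" else n - i - L
                hits.append(MotifHit(motif.motif_id, record.seq_id, start, L, strand, window))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def pwm_scan(
    seq: Union[str, SequenceRecord],
    motif: Motif,
    strands: str = "both",
    threshold: Optional[float] = None,
) -> List[MotifHit]:
    """Windows whose log2-odds PWM score reaches the motif's threshold.

    ``score = sum_j log2(p_j(base) / bg(base))`` over motif positions.
    Subjects must be unambiguous A/C/G/T.
    """
    if motif.kind != "pwm":
        raise ValueError(f"motif {motif.motif_id!r} is not a PWM motif")
    record = _as_record(seq)
    bad = set(record.sequence) - set("ACGT")
    if bad:
        raise ValueError(
            f"PWM scanning needs an unambiguous subject; {record.seq_id!r} "
            f"contains {sorted(bad)}"
        )
    cutoff = motif.threshold if threshold is None else threshold
    logodds = np.log2(motif.matrix / motif.background[:, None])
    L = motif.matrix.shape[1]
    n = len(record)
    hits: List[MotifHit] = []
    for strand, subject in _strand_views(record, strands):
        idx = np.fromiter((_BASE_INDEX[b] for b in subject), dtype=int, count=n)
        for i in range(n - L + 1):
            score = float(logodds[idx[i : i + L], np.arange(L)].sum())
            if score >= cutoff:
                start = i if strand == "+" else n - i - L
                hits.append(
                    MotifHit(
                        motif.motif_id,
                        record.seq_id,
                        start,
                        L,
                        strand,
                        subject[i : i + L],
                        score=score,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan(seq, motif: Motif, strands: str = "both") -> List[MotifHit]:
    """Dispatch on motif kind."""
    if motif.kind == "iupac":
        return iupac_scan(seq, motif, strands)
    return pwm_scan(seq, motif, strands)


def pwm_from_sites(
    motif_id: str,
    sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
    threshold: float = 0.0,
) -> Motif:
    """Build a probability PWM from aligned equal-length site strings."""
    sites = [s.upper() for s in sites]
    if not sites:
        raise ValueError("at least one site is required")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("sites must all have the same length")
    counts = np.full((4, L), float(pseudocount))
    for s in sites:
        for j, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValueError(f"site {s!r} contains non-ACGT base {b!r}")
            counts[_BASE_INDEX[b], j] += 1.0
    matrix = counts / counts.sum(axis=0, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return Motif(motif_id, "pwm", matrix=matrix, background=bg, threshold=threshold)


@dataclass
class AlleleDiffReport:
    """Motif hits gained, lost or kept when a SNP switches alleles.

    Hits whose window does not cover the variant are provably identical for
    the two alleles and are reported once under ``invariant``.  ``gained``
    are present only with ``allele_b``, ``lost`` only with ``allele_a``;
    ``shared_variant`` hits cover the variant but survive the substitution.
    """

    seq_id: str
    template: str
    variant_pos: int
    allele_a: str
    allele_b: str
    hits_a: List[MotifHit]
    hits_b: List[MotifHit]
    gained: List[MotifHit]
    lost: List[MotifHit]
    shared_variant: List[MotifHit]
    invariant: List[MotifHit]

    def to_dict(self) -> dict:
        def ser(hits):
            return [
                {
                    "motif_id": h.motif_id,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "site": h.site,
                    "score": h.score,
                }
                for h in hits
            ]

        return {
            "seq_id": self.seq_id,
            "variant_pos": self.variant_pos,
            "alleles": [self.allele_a, self.allele_b],
            "gained": ser(self.gained),
            "lost": ser(self.lost),
            "shared_at_variant": ser(self.shared_variant),
            "invariant": ser(self.invariant),
        }


def allele_differential_scan(
    template: Union[str, SequenceRecord],
    variant_pos: int,
    allele_a: str,
    allele_b: str,
    motifs: Iterable[Motif],
    strands: str = "both",
) -> AlleleDiffReport:
    """Scan both allele-substituted sequences and classify hits at the variant.

    ``template`` supplies the invariant context; the base at ``variant_pos``
    is replaced by ``allele_a`` and ``allele_b`` in turn.  Identical alleles
    give an empty gained/lost report.
    """
    record = _as_record(template)
    n = len(record)
    if not 0 <= variant_pos < n:
        raise ValueError(f"variant position {variant_pos} outside sequence of length {n}")
    allele_a, allele_b = allele_a.upper(), allele_b.upper()
    for a in (allele_a, allele_b):
        if a not in _BASE_INDEX:
            raise ValueError(f"allele {a!r} must be a single A/C/G/T base")
    seqs = {}
    for label, allele in (("a", allele_a), ("b", allele_b)):
        s = record.sequence[:variant_pos] + allele + record.sequence[variant_pos + 1 :]
        seqs[label] = SequenceRecord(f"{record.seq_id}:{allele}", s)
    hits_a: List[MotifHit] = []
    hits_b: List[MotifHit] = []
    for motif in motifs:
        hits_a.extend(scan(seqs["a"], motif, strands))
        hits_b.extend(scan(seqs["b"], motif, strands))
    at_var_a = {h.key(): h for h in hits_a if h.overlaps(variant_pos)}
    at_var_b = {h.key(): h for h in hits_b if h.overlaps(variant_pos)}
    gained = [at_var_b[k] for k in sorted(at_var_b.keys() - at_var_a.keys())]
    lost = [at_var_a[k] for k in sorted(at_var_a.keys() - at_var_b.keys())]
    shared = [at_var_a[k] for k in sorted(at_var_a.keys() & at_var_b.keys())]
    invariant = sorted(
        (h for h in hits_a if not h.overlaps(variant_pos)),
        key=lambda h: (h.motif_id, h.start, h.strand),
    )
    return AlleleDiffReport(
        seq_id=record.seq_id,
        template=record.sequence,
        variant_pos=variant_pos,
        allele_a=allele_a,
        allele_b=allele_b,
        hits_a=hits_a,
        hits_b=hits_b,
        gained=gained,
        lost=lost,
        shared_variant=shared,
        invariant=invariant,
    )


def load_motifs_json(source) -> List[Motif]:
    """Read a motif list from a JSON file path, file object or string."""
    if hasattr(source, "read"):
        data = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("["):
            data = json.loads(text)
        else:
            with open(text) as fh:
                data = json.load(fh)
    motifs = []
    for entry in data:
        if entry["kind"] == "iupac":
            motifs.append(Motif(entry["motif_id"], "iupac", pattern=entry["pattern"]))
        else:
            matrix = np.array([entry["matrix"][b] for b in "ACGT"], dtype=float)
            bg = np.asarray(entry.get("background", [0.25] * 4), dtype=float)
            motifs.append(
                Motif(
                    entry["motif_id"],
                    "pwm",
                    matrix=matrix,
                    background=bg,
                    threshold=float(entry.get("threshold", 0.0)),
                )
            )
    return motifs


def motifs_to_json(motifs: Iterable[Motif]) -> str:
    out = []
    for m in motifs:
        if m.kind == "iupac":
            out.append({"motif_id": m.motif_id, "kind": "iupac", "pattern": m.pattern})
        else:
            out.append(
                {
                    "motif_id": m.motif_id,
                    "kind": "pwm",
                    "matrix": {b: m.matrix[_BASE_INDEX[b]].tolist() for b in "ACGT"},
                    "background": m.background.tolist(),
                    "threshold": m.threshold,
                }
            )
    return json.dumps(out, indent=2)
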