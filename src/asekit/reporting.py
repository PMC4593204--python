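"""Cohort-table parsing, report rendering and run manifests.

The cohort table is the tidy per-sample genotype listing a candidate-SNP
study publishes: one row per sample with optional age/histology columns and
one genotype column per locus, homozygotes allowed in single-letter
shorthand ("A" for "A/A").  Reports mirror the published layouts: genotype
and allele frequency tables with one-decimal percentages and two-decimal
Fisher p-values, haplotype/LD blocks with three-decimal frequencies, an ASE
calling summary and a motif gain/loss section.  Every command-line run
writes a :class:`RunManifest` capturing the resolved configuration, input
digests and seed, which is sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .loci import LocusDefinition
from .popgen import (
    GenotypeCounts,
    LDStats,
    TestResult,
    allele_counts_from_genotypes,
    genotype_frequency_table,
    round_half_up,
)

__all__ = [
    "parse_cohort_table",
    "write_cohort_table",
    "normalize_genotype",
    "render_summary",
    "RunManifest",
]

_META_COLUMNS = {"sample_id", "cohort", "age", "histology"}


def normalize_genotype(value: str) -> str:
    """Expand homozygote shorthand: "A" -> "A/A"; pass "A/G" through."""
    v = str(value).strip()
    if "/" in v:
        parts = v.split("/")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"malformed genotype {value!r}")
        return f"{parts[0].upper()}/{parts[1].upper()}"
    if len(v) != 1:
        raise ValueError(f"malformed genotype {value!r}")
    v = v.upper()
    return f"{v}/{v}"


def parse_cohort_table(
    source,
    loci: Optional[Mapping[str, LocusDefinition]] = None,
    locus_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Read and validate a cohort genotype table (TSV/CSV with header).

    Genotype columns are ``locus_columns`` if given, otherwise every column
    that is not sample_id/cohort/age/histology.  Shorthand homozygotes are
    expanded; when ``loci`` provides a definition for a column, genotypes
    are validated against its alleles.  Malformed genotypes and duplicate
    sample ids raise errors naming the offending row and column.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = "," if str(source).endswith(".csv") else "\t"
        df = pd.read_csv(source, sep=sep, dtype=str)
    if df.empty and "sample_id" not in df.columns:
        import warnings

        warnings.warn("cohort table is empty")
        return pd.DataFrame(columns=["sample_id"])
    if "sample_id" not in df.columns:
        raise ValueError("cohort table needs a sample_id column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id(s): {sorted(set(dup))}")
    cols = list(locus_columns) if locus_columns else [
        c for c in df.columns if c not in _META_COLUMNS
    ]
    for col in cols:
        normed = []
        for i, value in enumerate(df[col]):
            try:
                g = normalize_genotype(value)
                if loci and col in loci:
                    loci[col].genotype_index(g)
            except ValueError as err:
                sample = df["sample_id"].iloc[i]
                raise ValueError(f"row {sample!r}, column {col!r}: {err}") from None
            normed.append(g)
        df[col] = normed
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _genotype_section(
    lines: List[str],
    label: str,
    counts_by_cohort: Mapping[str, GenotypeCounts],
    genotype_p: Optional[TestResult] = None,
    allele_p: Optional[TestResult] = None,
) -> None:
    first = next(iter(counts_by_cohort.values()))
    locus = first.locus
    a1, a2 = locus.alleles
    lines.append(f"{label}")
    header = (
        f"{'cohort':<22}{a1 + '/' + a1:>12}{a1 + '/' + a2:>12}{a2 + '/' + a2:>12}"
        f"{a1:>12}{a2:>12}"
    )
    lines.append(header)
    for cohort, gc in counts_by_cohort.items():
        _, pct = genotype_frequency_table(
            [f"{a1}/{a1}"] * gc.n_11 + [f"{a1}/{a2}"] * gc.n_12 + [f"{a2}/{a2}"] * gc.n_22,
            locus,
        )
        alleles = allele_counts_from_genotypes(gc)
        cells = [
            f"{gc.n_11} ({pct[f'{a1}/{a1}']:.1f}%)",
            f"{gc.n_12} ({pct[f'{a1}/{a2}']:.1f}%)",
            f"{gc.n_22} ({pct[f'{a2}/{a2}']:.1f}%)",
            f"{alleles[a1]['count']} ({alleles[a1]['percent']:.1f}%)",
            f"{alleles[a2]['count']} ({alleles[a2]['percent']:.1f}%)",
        ]
        lines.append(f"{cohort:<22}" + "".join(f"{c:>12}" for c in cells))
    if genotype_p is not None:
        lines.append(f"  genotype p = {round_half_up(genotype_p.p_value, 2):.2f}")
    if allele_p is not None:
        lines.append(f"  allele p   = {round_half_up(allele_p.p_value, 2):.2f}")
    lines.append("")


def render_summary(
    calls=None,
    popgen: Optional[Mapping[str, Mapping[str, GenotypeCounts]]] = None,
    popgen_tests: Optional[Mapping[str, Mapping[str, TestResult]]] = None,
    haplotypes=None,
    ld: Optional[LDStats] = None,
    diff=None,
    path=None,
) -> str:
    """Render the available analysis sections into one deterministic report.

    Parameters mirror the pipeline stages: ``calls`` is an
    :class:`~asekit.ase.AllelicExpressionResults`; ``popgen`` maps locus ->
    cohort -> :class:`GenotypeCounts` (with optional Fisher results in
    ``popgen_tests`` keyed ``genotype``/``allele``); ``haplotypes`` is a
    :class:`~asekit.popgen.TwoLocusHaplotypeResults`; ``ld`` adds the LD
    block; ``diff`` an :class:`~asekit.motif.AlleleDiffReport`.  Absent
    sections are omitted.
    """
    lines: List[str] = []
    if popgen:
        lines.append("Genotype and allele frequencies")
        lines.append("=" * 82)
        for locus_label, by_cohort in popgen.items():
            tests = (popgen_tests or {}).get(locus_label, {})
            _genotype_section(
                lines,
                locus_label,
                by_cohort,
                genotype_p=tests.get("genotype"),
                allele_p=tests.get("allele"),
            )
    if haplotypes is not None:
        lines.append(haplotypes.summary())
        lines.append("")
    elif ld is not None:
        lines.append("Linkage disequilibrium")
        lines.append(f"  D = {ld.D:.4f}")
        if ld.d_prime is not None:
            lines.append(f"  D' = {ld.d_prime:.3f}")
            lines.append(f"  r2 = {ld.r_squared:.3f}")
        lines.append("")
    if calls is not None:
        lines.append(calls.summary())
        lines.append("")
    if diff is not None:
        d = diff.to_dict()
        lines.append(
            f"Allele-differential motif scan at {diff.seq_id} "
            f"position {diff.variant_pos + 1} ({diff.allele_a}->{diff.allele_b})"
        )
        for key in ("lost", "gained", "shared_at_variant"):
            lines.append(f"  {key}:")
            if not d[key]:
                lines.append("    (none)")
            for h in d[key]:
                score = "" if h["score"] is None else f" score={h['score']:.2f}"
                lines.append(
                    f"    {h['motif_id']} at {h['start'] + 1}-{h['end']} "
                    f"({h['strand']}) site={h['site']}{score}"
                )
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Full provenance of one command-line run."""

    command: str
    config: dict
    inputs: Dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    tool_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @classmethod
    def capture(cls, command: str, config: dict, input_paths: Sequence = (), seed=None):
        return cls(
            command=command,
            config=config,
            inputs={str(p): _digest(p) for p in input_paths},
            seed=seed,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
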