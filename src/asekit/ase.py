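"""Calibrated allelic-ratio ASE calling from fluorescent peak heights.

The laboratory observable is a pair of peak heights per sample, marker SNP
and analyte (gDNA or cDNA).  Quantification proceeds in four steps:

1. *Calibrate*: known-ratio two-allele standard mixtures estimate a single
   multiplicative allele-specific signal bias per marker, fitted in log
   space (the geometric mean of observed/known ratios).
2. *Gate heterozygotes*: only samples with two genomic peaks (minor/major
   height fraction >= ``min_minor_fraction``, or an explicit genotype
   table) are informative for ASE.
3. *Exclude mono-allelic amplification*: a corrected genomic ratio beyond
   ``mono_tau``-fold in either direction indicates a somatic copy-number
   imbalance, and the sample cannot be evaluated for ASE.
4. *Call*: the relative expression ratio rho = corrected cDNA ratio /
   corrected gDNA ratio is ASE-positive when the symmetric imbalance
   ``max(rho, 1/rho) - 1`` exceeds the threshold (default 20%), the
   convention used to call allelic expression differences "beyond 20%".

:class:`AllelicExpressionModel` bundles the four steps behind a
``fit()`` -> :class:`AllelicExpressionResults` interface; the per-step
functions are exposed for direct use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PipelineConfig",
    "CalibrationCurve",
    "ASECall",
    "fit_calibration",
    "correct_ratio",
    "classify_heterozygote",
    "call_ase",
    "run_pipeline",
    "AllelicExpressionModel",
    "AllelicExpressionResults",
]

STATUS_POSITIVE = "ase_positive"
STATUS_NEGATIVE = "ase_negative"
STATUS_EXCLUDED = "excluded_monoallelic"
STATUS_NOT_HET = "not_heterozygous"


@dataclass(frozen=True)
class PipelineConfig:
    """Calling thresholds.

    ase_threshold : float
        Relative difference between corrected cDNA and gDNA allelic ratios
        above which a sample is ASE-positive (strict inequality).  0.20
        operationalises the "more than 20% difference" convention.
    mono_tau : float
        Corrected genomic ratio (either orientation) beyond which the
        sample is excluded as mono-allelic amplification.
    min_minor_fraction : float
        Minimum genomic minor/major peak-height fraction for a sample to be
        gated heterozygous (inclusive bound).
    """

    ase_threshold: float = 0.20
    mono_tau: float = 3.0
    min_minor_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.ase_threshold > 0:
            raise ValueError(f"ase_threshold must be > 0, got {self.ase_threshold}")
        if not self.mono_tau > 1:
            raise ValueError(f"mono_tau must be > 1, got {self.mono_tau}")
        if not 0 < self.min_minor_fraction < 0.5:
            raise ValueError(
                f"min_minor_fraction must be in (0, 0.5), got {self.min_minor_fraction}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-marker multiplicative allele-1 signal excess, fitted in log space."""

    locus_id: str
    bias: float
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if not self.bias > 0:
            raise ValueError(f"bias must be > 0, got {self.bias}")
        if self.n_points < 1:
            raise ValueError("calibration needs at least one standard")


@dataclass(frozen=True)
class ASECall:
    """Per-sample, per-marker verdict."""

    sample_id: str
    locus_id: str
    corrected_gdna_ratio: float
    corrected_cdna_ratio: float
    expression_ratio: float
    imbalance: float
    status: str


def fit_calibration(
    standards: Union[pd.DataFrame, Iterable],
    locus_id: Optional[str] = None,
) -> CalibrationCurve:
    """Estimate the allele-specific signal bias from known-ratio standards.

    ``bias = exp(mean(log(observed ratio) - log(known ratio)))`` over all
    standards; ``residual_sd`` is the standard deviation of those log
    residuals (0 for a single point).  Standards are two-allele mixtures by
    construction, so a zero peak height is rejected.
    """
    if isinstance(standards, pd.DataFrame):
        df = standards
        if locus_id is not None:
            df = df[df["locus_id"] == locus_id]
        if len(df) == 0:
            raise ValueError(f"no standards for locus {locus_id!r}")
        known = df["known_ratio"].to_numpy(dtype=float)
        h1 = df["height_allele1"].to_numpy(dtype=float)
        h2 = df["height_allele2"].to_numpy(dtype=float)
        lid = locus_id or str(df["locus_id"].iloc[0])
    else:
        rows = list(standards)
        if not rows:
            raise ValueError("at least one calibration standard is required")
        known = np.array([r[0] for r in rows], dtype=float)
        h1 = np.array([r[1] for r in rows], dtype=float)
        h2 = np.array([r[2] for r in rows], dtype=float)
        lid = locus_id or ""
    if np.any(~np.isfinite(known)) or np.any(known <= 0):
        raise ValueError("every standard needs a finite known_ratio > 0")
    if np.any(h1 <= 0) or np.any(h2 <= 0):
        raise ValueError(
            f"calibration standards for {lid!r} contain a non-positive peak height"
        )
    resid = np.log(h1 / h2) - np.log(known)
    bias = float(np.exp(resid.mean()))
    sd = float(resid.std(ddof=1)) if len(resid) > 1 else 0.0
    return CalibrationCurve(locus_id=lid, bias=bias, n_points=len(resid), residual_sd=sd)


def correct_ratio(raw_ratio: float, curve: CalibrationCurve) -> float:
    """Divide an observed allelic ratio by the fitted signal bias."""
    if not raw_ratio > 0:
        raise ValueError(f"raw ratio must be > 0, got {raw_ratio}")
    return raw_ratio / curve.bias


def classify_heterozygote(
    height_allele1: float,
    height_allele2: float,
    config: PipelineConfig = PipelineConfig(),
) -> bool:
    """Gate on genomic peaks: heterozygous iff minor/major >= min_minor_fraction."""
    h1, h2 = float(height_allele1), float(height_allele2)
    if h1 < 0 or h2 < 0 or not (math.isfinite(h1) and math.isfinite(h2)):
        raise ValueError("peak heights must be finite and non-negative")
    if h1 == 0 and h2 == 0:
        raise ValueError("both peak heights are zero; record is unusable")
    return min(h1, h2) / max(h1, h2) >= config.min_minor_fraction


def call_ase(
    corrected_gdna_ratio: float,
    corrected_cdna_ratio: float,
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "",
    locus_id: str = "",
) -> ASECall:
    """Classify one heterozygous sample from its corrected allelic ratios."""
    g, c = float(corrected_gdna_ratio), float(corrected_cdna_ratio)
    if not g > 0 or not c > 0:
        raise ValueError("corrected ratios must be > 0")
    rho = c / g
    imbalance = max(rho, 1.0 / rho) - 1.0
    if max(g, 1.0 / g) > config.mono_tau:
        status = STATUS_EXCLUDED
    elif imbalance > config.ase_threshold:
        status = STATUS_POSITIVE
    else:
        status = STATUS_NEGATIVE
    return ASECall(sample_id, locus_id, g, c, rho, imbalance, status)


def _is_standard(analyte: pd.Series) -> pd.Series:
    return analyte.str.lower() == "standard"


class AllelicExpressionModel:
    """ASE calling model over a tidy peak-height table.

    Parameters
    ----------
    peaks : DataFrame
        Columns ``sample_id, locus_id, analyte, height_allele1,
        height_allele2`` (+ ``known_ratio`` for standard rows).  Analyte is
        ``gDNA``, ``cDNA`` or ``standard``; standard rows may also be given
        separately via ``standards``.
    standards : DataFrame, optional
        Additional calibration rows in the same schema.
    config : PipelineConfig
    genotypes : DataFrame, optional
        Columns ``sample_id, locus_id, genotype`` ("A/G" style).  When
        present for a record, the genotype overrides peak-based gating.
    bias_override : mapping, optional
        ``locus_id -> bias``; used for markers without standards (e.g. 1.0
        for an unbiased assay).
    cohorts : mapping, optional
        ``sample_id -> cohort label`` for the per-cohort summary.
    """

    def __init__(
        self,
        peaks: pd.DataFrame,
        standards: Optional[pd.DataFrame] = None,
        config: PipelineConfig = PipelineConfig(),
        genotypes: Optional[pd.DataFrame] = None,
        bias_override: Optional[Mapping[str, float]] = None,
        cohorts: Optional[Mapping[str, str]] = None,
    ) -> None:
        required = {"sample_id", "locus_id", "analyte", "height_allele1", "height_allele2"}
        missing = required - set(peaks.columns)
        if missing:
            raise ValueError(f"peak table is missing columns {sorted(missing)}")
        peaks = peaks.copy()
        if standards is not None:
            peaks = pd.concat([peaks, standards], ignore_index=True)
        self.standards = peaks[_is_standard(peaks["analyte"])].copy()
        self.peaks = peaks[~_is_standard(peaks["analyte"])].copy()
        self.config = config
        self.bias_override = dict(bias_override or {})
        self.cohorts = dict(cohorts or {})
        self._genotypes: Dict[tuple, str] = {}
        if genotypes is not None:
            for row in genotypes.itertuples(index=False):
                self._genotypes[(row.sample_id, row.locus_id)] = row.genotype

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "AllelicExpressionModel":
        return cls(pd.read_csv(path, sep="\t", na_values=["NA"]), **kwargs)

    def _curves(self) -> Dict[str, CalibrationCurve]:
        curves: Dict[str, CalibrationCurve] = {}
        markers = sorted(self.peaks["locus_id"].unique())
        for locus in markers:
            if locus in self.bias_override:
                curves[locus] = CalibrationCurve(locus, float(self.bias_override[locus]), 1, 0.0)
            elif (self.standards["locus_id"] == locus).any():
                curves[locus] = fit_calibration(self.standards, locus)
            else:
                raise ValueError(
                    f"marker {locus!r} has no calibration standards and no bias "
                    "override; pass bias_override={" + repr(locus) + ": 1.0} for an "
                    "unbiased assay"
                )
        return curves

    def fit(self) -> "AllelicExpressionResults":
        cfg = self.config
        curves = self._curves()
        calls: List[ASECall] = []
        not_het: List[tuple] = []
        missing_cdna: List[tuple] = []
        by_key: Dict[tuple, Dict[str, pd.Series]] = {}
        for row in self.peaks.itertuples(index=False):
            by_key.setdefault((row.sample_id, row.locus_id), {})[row.analyte] = row
        for (sample, locus), recs in sorted(by_key.items()):
            if "gDNA" not in recs:
                continue
            g = recs["gDNA"]
            genotype = self._genotypes.get((sample, locus))
            if genotype is not None:
                alleles = genotype.split("/")
                het = len(set(alleles if len(alleles) == 2 else alleles * 2)) == 2
            else:
                het = classify_heterozygote(g.height_allele1, g.height_allele2, cfg)
            if not het:
                not_het.append((sample, locus))
                continue
            if "cDNA" not in recs:
                missing_cdna.append((sample, locus))
                continue
            c = recs["cDNA"]
            curve = curves[locus]
            g_corr = correct_ratio(g.height_allele1 / g.height_allele2, curve)
            c_corr = correct_ratio(c.height_allele1 / c.height_allele2, curve)
            calls.append(call_ase(g_corr, c_corr, cfg, sample, locus))
        return AllelicExpressionResults(
            model=self,
            calibration=curves,
            calls=calls,
            not_heterozygous=not_het,
            missing_cdna=missing_cdna,
        )


@dataclass
class AllelicExpressionResults:
    """Fitted calibration curves plus per-sample ASE calls and summaries."""

    model: AllelicExpressionModel
    calibration: Dict[str, CalibrationCurve]
    calls: List[ASECall]
    not_heterozygous: List[tuple]
    missing_cdna: List[tuple]

    @property
    def calls_frame(self) -> pd.DataFrame:
        rows = [asdict(c) for c in self.calls]
        rows += [
            {
                "sample_id": s,
                "locus_id": l,
                "corrected_gdna_ratio": np.nan,
                "corrected_cdna_ratio": np.nan,
                "expression_ratio": np.nan,
                "imbalance": np.nan,
                "status": STATUS_NOT_HET,
            }
            for s, l in self.not_heterozygous
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "locus_id",
                "corrected_gdna_ratio",
                "corrected_cdna_ratio",
                "expression_ratio",
                "imbalance",
                "status",
            ],
        )
        return df.sort_values(["locus_id", "sample_id"], ignore_index=True)

    def summary_dict(self) -> dict:
        cohorts = self.model.cohorts
        per: Dict[tuple, Dict[str, int]] = {}

        def bucket(sample, locus):
            key = (cohorts.get(sample, "all"), locus)
            return per.setdefault(
                key,
                {
                    "n_samples": 0,
                    "heterozygous": 0,
                    "excluded_monoallelic": 0,
                    "evaluable": 0,
                    "ase_positive": 0,
                    "ase_negative": 0,
                },
            )

        for s, l in self.not_heterozygous:
            bucket(s, l)["n_samples"] += 1
        for s, l in self.missing_cdna:
            b = bucket(s, l)
            b["n_samples"] += 1
            b["heterozygous"] += 1
        for c in self.calls:
            b = bucket(c.sample_id, c.locus_id)
            b["n_samples"] += 1
            b["heterozygous"] += 1
            if c.status == STATUS_EXCLUDED:
                b["excluded_monoallelic"] += 1
            else:
                b["evaluable"] += 1
                b["ase_positive" if c.status == STATUS_POSITIVE else "ase_negative"] += 1
        out = {
            "calibration": {
                l: {"bias": c.bias, "n_points": c.n_points, "residual_sd": c.residual_sd}
                for l, c in sorted(self.calibration.items())
            },
            "groups": [
                {"cohort": k[0], "locus_id": k[1], **v} for k, v in sorted(per.items())
            ],
            "missing_cdna": [list(x) for x in sorted(self.missing_cdna)],
        }
        return out

    def summary(self) -> str:
        s = self.summary_dict()
        lines = ["Allele-specific expression calling", "=" * 50]
        for locus, cal in s["calibration"].items():
            lines.append(
                f"calibration {locus}: bias={cal['bias']:.4f} "
                f"(n={cal['n_points']}, residual sd={cal['residual_sd']:.4f})"
            )
        lines.append("-" * 50)
        lines.append(
            f"{'cohort':<14}{'marker':<12}{'het':>5}{'excl':>6}{'eval':>6}{'ASE+':>6}"
        )
        for g in s["groups"]:
            lines.append(
                f"{g['cohort']:<14}{g['locus_id']:<12}{g['heterozygous']:>5}"
                f"{g['excluded_monoallelic']:>6}{g['evaluable']:>6}{g['ase_positive']:>6}"
            )
        if s["missing_cdna"]:
            lines.append(f"flagged (gDNA without cDNA): {s['missing_cdna']}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        df = self.calls_frame.copy()
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")

    def to_json(self, path=None) -> str:
        text = json.dumps(self.summary_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_pipeline(
    peaks: pd.DataFrame,
    standards: Optional[pd.DataFrame] = None,
    config: PipelineConfig = PipelineConfig(),
    **kwargs,
) -> AllelicExpressionResults:
    """Convenience wrapper: build the model and fit in one call."""
    return AllelicExpressionModel(peaks, standards=standards, config=config, **kwargs).fit()
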