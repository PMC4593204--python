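import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from asekit import datasets
from asekit.ase import AllelicExpressionModel
from asekit.simulate import (
    DEFAULT_STANDARD_RATIOS,
    CohortSample,
    SimulationConfig,
    assign_expression_model,
    default_study_table,
    emit_peak_signals,
    emit_standard_series,
)


@pytest.fixture(scope="session")
def study_loci():
    return datasets.study_loci()


@pytest.fixture(scope="session")
def emca_cohort():
    return datasets.emca_cohort(normalize=True)


def recovery_experiment(
    seed: int,
    n_het: int = 200,
    bias: float = 1.5,
    noise_cv: float = 0.05,
    magnitude: float = 1.5,
    prevalence: float = 0.1,
):
    """ASE truth-recovery experiment on a cohort of double heterozygotes.

    Returns (fitted bias, true positives, false negatives, false positives,
    true negatives) at the rs1690916 read-out marker.
    """
    table = default_study_table()
    cfg = SimulationConfig(
        haplotype_table=table,
        ase_prevalence=prevalence,
        ase_magnitude=magnitude,
        bias_per_marker={"rs1690916": bias},
        noise_cv=noise_cv,
        monoallelic_fraction=0.0,
        seed=seed,
    )
    cohort = [
        CohortSample(f"S{i:03d}", "cancer", (("C", "T", "G"), ("T", "T", "A")))
        for i in range(n_het)
    ]
    cohort = assign_expression_model(cohort, cfg)
    peaks = emit_peak_signals(cohort, cfg)
    marker = next(l for l in table.loci if l.locus_id == "rs1690916")
    standards = emit_standard_series(marker, DEFAULT_STANDARD_RATIOS, cfg, 3)
    results = AllelicExpressionModel(peaks, standards=standards).fit()
    calls = {c.sample_id: c for c in results.calls if c.locus_id == "rs1690916"}
    tp = fn = fp = tn = 0
    for s in cohort:
        positive = calls[s.sample_id].status == "ase_positive"
        if s.ase_truth:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return results.calibration["rs1690916"].bias, tp, fn, fp, tn
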