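"""Frequency tables, exact tests, haplotype estimation and LD statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as scipy_stats

from asekit import datasets
from asekit.loci import HaplotypeFrequencyTable, LocusDefinition
from asekit.popgen import (
    GenotypeCounts,
    TwoLocusHaplotypeModel,
    allele_counts_from_genotypes,
    fisher_exact,
    genotype_frequency_table,
    haplotype_frequencies_direct,
    haplotype_frequencies_em,
    haplotypes_from_allele_freqs,
    hwe_chisq,
    hwe_exact,
    ld_from_haplotypes,
)
from oracles import em_grid_oracle, fisher_oracle, hwe_oracle

SNP55 = LocusDefinition("SNP55", ("C", "T"), role="functional")
SNP309 = LocusDefinition("SNP309", ("T", "G"), role="functional")


class TestFrequencyTables:
    def test_cancer_free_snp55_percentages(self):
        genotypes = ["C/C"] * 17 + ["C/T"] * 24 + ["T/T"] * 4
        gc, pct = genotype_frequency_table(genotypes, SNP55)
        assert gc.as_row() == (17, 24, 4)
        assert pct == {"C/C": 37.8, "C/T": 53.3, "T/T": 8.9}

    def test_empty_list_reports_absent_percentages(self):
        gc, pct = genotype_frequency_table([], SNP55)
        assert gc.as_row() == (0, 0, 0)
        assert pct is None

    def test_single_heterozygote(self):
        gc, pct = genotype_frequency_table(["C/T"], SNP55)
        assert gc.as_row() == (0, 1, 0)
        assert pct == {"C/C": 0.0, "C/T": 100.0, "T/T": 0.0}

    def test_foreign_allele_rejected_with_sample_number(self):
        with pytest.raises(ValueError, match="#2"):
            genotype_frequency_table(["C/T", "A/G"], SNP55)

    def test_allele_counts_from_published_rows(self):
        alleles = allele_counts_from_genotypes(GenotypeCounts(SNP55, 17, 24, 4))
        assert alleles["C"] == {"count": 58, "percent": 64.4}
        assert alleles["T"] == {"count": 32, "percent": 35.6}
        alleles = allele_counts_from_genotypes(GenotypeCounts(SNP309, 12, 24, 9))
        assert alleles["T"]["count"] == 48
        assert alleles["G"]["count"] == 42
        assert alleles["T"]["percent"] == 53.3 and alleles["G"]["percent"] == 46.7

    def test_zero_counts(self):
        alleles = allele_counts_from_genotypes(GenotypeCounts(SNP55, 0, 0, 0))
        assert alleles["C"]["count"] == 0 and alleles["C"]["percent"] is None

    @given(
        st.tuples(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_percentages_sum_to_hundred_within_rounding(self, counts):
        genotypes = (
            ["C/C"] * counts[0] + ["C/T"] * counts[1] + ["T/T"] * counts[2]
        )
        _, pct = genotype_frequency_table(genotypes, SNP55)
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.2)
        gc, _ = genotype_frequency_table(genotypes, SNP55)
        assert gc.allele1_count + gc.allele2_count == 2 * gc.n


class TestFisherExact:
    def test_symmetric_table_gives_one(self):
        assert fisher_exact([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table, printed",
        [
            ([[17, 24, 4], [17, 22, 6]], 0.87),
            ([[58, 32], [56, 34]], 0.88),
            ([[12, 24, 9], [14, 21, 10]], 0.85),
            ([[48, 42], [49, 41]], 1.00),
        ],
    )
    def test_reproduces_published_p_values(self, table, printed):
        p = fisher_exact(table).p_value
        assert round(p, 2) == pytest.approx(printed)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0

    def test_agrees_with_scipy_on_2x2(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            ours = fisher_exact(t).p_value
            ref = scipy_stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_agrees_with_rational_oracle_on_2x3(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            t = rng.integers(0, 10, size=(2, 3))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact(t).p_value == pytest.approx(
                fisher_oracle(t), rel=1e-9
            )

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError, match="2x2 or 2x3"):
            fisher_exact([[1, 2, 3, 4]])


class TestHWE:
    def test_monomorphic_locus(self):
        res = hwe_exact(GenotypeCounts(SNP55, 20, 0, 0))
        assert res.p_value == 1.0
        assert "monomorphic" in res.note

    @pytest.mark.parametrize("counts", [(17, 24, 4), (12, 24, 9)])
    def test_published_cohorts_consistent_with_equilibrium(self, counts):
        assert hwe_exact(GenotypeCounts(SNP55, *counts)).p_value > 0.05

    def test_agrees_with_rational_oracle_small_n(self):
        for n11, n12, n22 in itertools.product(range(8), repeat=3):
            if n11 + n12 + n22 == 0:
                continue
            ours = hwe_exact(GenotypeCounts(SNP55, n11, n12, n22)).p_value
            assert ours == pytest.approx(hwe_oracle(n11, n12, n22), rel=1e-9)

    def test_chisq_variant_agrees_in_direction(self):
        gc = GenotypeCounts(SNP55, 30, 0, 30)  # extreme heterozygote deficit
        assert hwe_exact(gc).p_value < 1e-6
        assert hwe_chisq(gc).p_value < 1e-6


class TestHaplotypes:
    def test_direct_frequencies_match_published_rounding(self):
        haps = (
            [("C", "T")] * 16 + [("C", "G")] * 42 + [("T", "T")] * 32
        )
        table = haplotype_frequencies_direct(haps, [SNP55, SNP309])
        assert round(table.frequency(("C", "T")), 3) == 0.178
        assert round(table.frequency(("C", "G")), 3) == 0.467
        assert round(table.frequency(("T", "T")), 3) == 0.356
        assert table.frequency(("T", "G")) == 0.0

    def test_single_haplotype(self):
        table = haplotype_frequencies_direct([("C", "T")] * 5, [SNP55, SNP309])
        assert table.frequency(("C", "T")) == 1.0

    def test_balanced_pair(self):
        table = haplotype_frequencies_direct(
            [("C", "T"), ("T", "G")] * 3, [SNP55, SNP309]
        )
        assert table.frequency(("C", "T")) == 0.5
        assert table.frequency(("T", "G")) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            haplotype_frequencies_direct([])

    def test_em_equals_gamete_counting_without_double_heterozygotes(self):
        j = [[3, 2, 0], [4, 0, 1], [2, 0, 5]]
        table, trace = haplotype_frequencies_em(j, loci=(SNP55, SNP309))
        # direct gamete counting on unambiguous genotypes
        expected = {  # chromosomes per gamete, counted by hand cell by cell
            ("C", "T"): 2 * 3 + 2 + 4,
            ("C", "G"): 2 + 1,
            ("T", "T"): 4 + 2 * 2,
            ("T", "G"): 1 + 2 * 5,
        }
        n = 2 * 17
        for hap, count in expected.items():
            assert table.frequency(hap) == pytest.approx(count / n, abs=1e-9)

    def test_em_loglik_nondecreasing_and_matches_grid_search(self, emca_cohort):
        loci = datasets.study_loci()
        model = TwoLocusHaplotypeModel.from_genotypes(
            emca_cohort["SNP55"], emca_cohort["SNP309"], (loci["SNP55"], loci["SNP309"])
        )
        res = model.fit()
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-10).all()
        grid = em_grid_oracle(model.joint_counts)
        em = np.array(
            [
                res.frequencies.frequency(h)
                for h in [("C", "T"), ("C", "G"), ("T", "T"), ("T", "G")]
            ]
        )
        assert np.abs(em - grid).max() < 2e-3

    def test_em_recovers_generating_frequencies(self):
        rng = np.random.default_rng(99)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        n = 2000
        haps = [("C", "T"), ("C", "G"), ("T", "T"), ("T", "G")]
        draws = rng.choice(4, size=(n, 2), p=freqs)
        j = np.zeros((3, 3), dtype=int)
        for a, b in draws:
            ca = (haps[a][0] == "T") + (haps[b][0] == "T")
            cb = (haps[a][1] == "G") + (haps[b][1] == "G")
            j[ca, cb] += 1
        table, _ = haplotype_frequencies_em(j, loci=(SNP55, SNP309))
        for hap, f in zip(haps, freqs):
            se = np.sqrt(f * (1 - f) / (2 * n))
            assert abs(table.frequency(hap) - f) < 3 * se + 2e-3

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            haplotype_frequencies_em(np.zeros((3, 3)))

    def test_solving_margins_with_absent_haplotype(self):
        table = haplotypes_from_allele_freqs(
            58 / 90, 48 / 90, absent=(1, 1), loci=(SNP55, SNP309)
        )
        assert round(table.frequency(("C", "T")), 3) == 0.178
        assert table.frequency(("T", "G")) == 0.0

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            haplotypes_from_allele_freqs(0.9, 0.9, absent=(0, 0))


class TestLD:
    def paper_table(self):
        return HaplotypeFrequencyTable.from_counts(
            [SNP55, SNP309],
            {("C", "T"): 16, ("C", "G"): 42, ("T", "T"): 32, ("T", "G"): 0},
        )

    def test_published_r_squared(self):
        stats = ld_from_haplotypes(self.paper_table())
        assert round(stats.r_squared, 3) == 0.483

    def test_independent_loci_have_zero_ld(self):
        table = HaplotypeFrequencyTable(
            [SNP55, SNP309],
            {
                ("C", "T"): 0.6 * 0.3, ("C", "G"): 0.6 * 0.7,
                ("T", "T"): 0.4 * 0.3, ("T", "G"): 0.4 * 0.7,
            },
        )
        stats = ld_from_haplotypes(table)
        assert stats.D == pytest.approx(0.0, abs=1e-12)
        assert stats.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_perfect_correlation(self):
        table = HaplotypeFrequencyTable(
            [SNP55, SNP309], {("C", "T"): 0.5, ("T", "G"): 0.5}
        )
        stats = ld_from_haplotypes(table)
        assert stats.d_prime == pytest.approx(1.0)
        assert stats.r_squared == pytest.approx(1.0)

    def test_monomorphic_locus_reports_undefined(self):
        table = HaplotypeFrequencyTable(
            [SNP55, SNP309], {("C", "T"): 0.4, ("C", "G"): 0.6}
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            stats = ld_from_haplotypes(table)
        assert stats.d_prime is None and stats.r_squared is None

    @given(
        f=st.tuples(
            st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)
        )
    )
    def test_r2_invariant_under_allele_relabelling(self, f):
        total = sum(f)
        f11, f12, f21, f22 = (x / total for x in f)
        base = HaplotypeFrequencyTable(
            [SNP55, SNP309],
            {("C", "T"): f11, ("C", "G"): f12, ("T", "T"): f21, ("T", "G"): f22},
        )
        swapped = HaplotypeFrequencyTable(
            [LocusDefinition("SNP55", ("T", "C")), SNP309],
            {("T", "T"): f21, ("T", "G"): f22, ("C", "T"): f11, ("C", "G"): f12},
        )
        a, b = ld_from_haplotypes(base), ld_from_haplotypes(swapped)
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-9)
        assert a.D == pytest.approx(-b.D, abs=1e-12)

    def test_results_object_summary(self):
        res = TwoLocusHaplotypeModel.from_phased(
            [h for h, c in datasets.cancer_free_haplotype_counts().items() for _ in range(c)],
            loci=(SNP55, SNP309),
        ).fit()
        text = res.summary()
        assert "0.178" in text and "0.483" in text


class TestCohortAggregation:
    def test_emca_table_reproduces_published_margins(self, emca_cohort, study_loci):
        # SNP55 and SNP309 genotype rows of the published comparison table
        gc55, _ = genotype_frequency_table(emca_cohort["SNP55"], study_loci["SNP55"])
        assert gc55.as_row() == (17, 22, 6)
        gc309, _ = genotype_frequency_table(emca_cohort["SNP309"], study_loci["SNP309"])
        assert gc309.as_row() == (14, 21, 10)
        # 3'UTR marker genotype table
        gc_utr, _ = genotype_frequency_table(
            emca_cohort["rs1690916"], study_loci["rs1690916"]
        )
        assert gc_utr.as_row() == (19, 20, 6)  # (G/G, G/A, A/A)
        # exon-1 marker heterozygote count (the published homozygote split
        # disagrees with the per-sample listing by one sample; see docs)
        gc_ex1, _ = genotype_frequency_table(
            emca_cohort["rs937283"], study_loci["rs937283"]
        )
        assert gc_ex1.n_12 == 20
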