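"""Allele harmonization decision rules and the HWE exact test."""

import math

import numpy as np
import pytest

from conftest import brute_hwe_exact
from snpmeta.config import PipelineConfig
from snpmeta.effects import extract_effect
from snpmeta.harmonize import (align_to_reference, eligibility_filter,
                               hwe_chisq_test, hwe_exact_test, hwe_test)
from snpmeta.meta import dersimonian_laird_meta
from snpmeta.records import (AlleleCounts, GenotypeCounts, ReferenceFrequency,
                             ReferenceTable, Statistics, StudyRecord)
from snpmeta.simulate import SimulationConfig, simulate_dataset


def _ref(minor="A", maf=0.20, major="G", snp="rs1", pop="EAS"):
    table = ReferenceTable()
    table.add(ReferenceFrequency(snp_id=snp, population=pop, minor_allele=minor,
                                 maf=maf, major_allele=major))
    return table


def _stat_record(a1, a2, freq, or_value=1.5, p=0.01):
    return StudyRecord(study_id="s", snp_id="rs1", ancestry="Asian",
                       design="case_control", allele_1=a1, allele_2=a2,
                       statistics=Statistics(or_value=or_value, p_value=p),
                       reported_freq_allele1=freq)


class TestAlignmentDecisions:
    def test_concordant_frequency_is_unchanged(self):
        h = align_to_reference(_stat_record("A", "G", 0.19), _ref(maf=0.20), "EAS")
        assert h.action == "unchanged"
        assert h.estimate.ae == pytest.approx(math.log(1.5))

    def test_discordant_frequency_switches_labels_and_negates(self):
        h = align_to_reference(_stat_record("A", "G", 0.82), _ref(maf=0.18), "EAS")
        assert h.action == "allele_switched"
        assert h.estimate.ae == pytest.approx(-math.log(1.5))

    def test_complementary_alleles_are_strand_flipped(self):
        h = align_to_reference(_stat_record("T", "C", 0.19), _ref(maf=0.20), "EAS")
        assert h.action == "strand_flipped"
        assert h.estimate.ae == pytest.approx(math.log(1.5))

    def test_strand_flip_then_switch(self):
        h = align_to_reference(_stat_record("T", "C", 0.82), _ref(maf=0.18), "EAS")
        assert h.action == "strand_flipped_and_switched"
        assert h.estimate.ae == pytest.approx(-math.log(1.5))

    def test_unmatched_alleles_excluded(self):
        h = align_to_reference(_stat_record("A", "C", 0.2), _ref(minor="A", major="G"), "EAS")
        assert h.action == "excluded_unresolved"
        assert h.estimate is None

    def test_absent_snp_passes_with_warning(self):
        h = align_to_reference(_stat_record("A", "G", 0.2), ReferenceTable(), "EAS")
        assert h.action == "unchanged"
        assert "absent" in h.note

    def test_major_labelled_allele1_reorients_to_minor(self):
        # study reports the major allele as allele_1; harmonized effect must
        # refer to the reference minor allele, so the sign flips
        h = align_to_reference(_stat_record("G", "A", 0.80), _ref(maf=0.20), "EAS")
        assert h.action == "unchanged"
        assert h.effect_allele == "A"
        assert h.estimate.ae == pytest.approx(-math.log(1.5))

    def test_subpopulation_drift_not_called_a_switch(self):
        # 0.35 vs MAF 0.20: deviation 0.15 < 0.2 threshold -> concordant
        h = align_to_reference(_stat_record("A", "G", 0.35), _ref(maf=0.20), "EAS")
        assert h.action == "unchanged"


class TestPalindromic:
    def test_ambiguity_window_excludes(self):
        h = align_to_reference(_stat_record("A", "T", 0.45), _ref(minor="A", major="T", maf=0.45), "EAS")
        assert h.action == "excluded_ambiguous"

    def test_oriented_by_concordant_frequency(self):
        h = align_to_reference(_stat_record("C", "G", 0.11), _ref(minor="C", major="G", maf=0.10), "EAS")
        assert h.action == "unchanged"
        assert h.estimate.ae == pytest.approx(math.log(1.5))

    def test_opposite_side_frequency_switches(self):
        h = align_to_reference(_stat_record("C", "G", 0.88), _ref(minor="C", major="G", maf=0.10), "EAS")
        assert h.action == "allele_switched"
        assert h.estimate.ae == pytest.approx(-math.log(1.5))

    def test_no_frequency_information_excludes(self):
        rec = StudyRecord(study_id="s", snp_id="rs1", ancestry="Asian",
                          design="case_control", allele_1="A", allele_2="T",
                          statistics=Statistics(or_value=1.5, p_value=0.01))
        h = align_to_reference(rec, _ref(minor="A", major="T", maf=0.10), "EAS")
        assert h.action == "excluded_ambiguous"


class TestSignCoherence:
    def test_switch_negates_and_preserves_magnitude(self):
        base = align_to_reference(_stat_record("A", "G", 0.19), _ref(maf=0.20), "EAS")
        switched = align_to_reference(_stat_record("A", "G", 0.82), _ref(maf=0.18), "EAS")
        assert switched.estimate.ae == pytest.approx(-base.estimate.ae)
        assert switched.estimate.se_ae == pytest.approx(base.estimate.se_ae)

    def test_pooled_estimate_invariant_to_reporting_strand(self):
        """Metamorphic: injecting strand errors must not move the pooled effect."""
        base = SimulationConfig(n_snps=6, theta=math.log(1.3), tau2=0.0,
                                strand_error_rate=0.0, trio_fraction=0.0,
                                stats_only_fraction=0.0, palindromic_fraction=0.0)
        noisy = SimulationConfig(n_snps=6, theta=math.log(1.3), tau2=0.0,
                                 strand_error_rate=0.6, trio_fraction=0.0,
                                 stats_only_fraction=0.0, palindromic_fraction=0.0)
        _, rec_a, ref = simulate_dataset(base, 314)
        _, rec_b, _ = simulate_dataset(noisy, 314)
        assert [r.study_id for r in rec_a] == [r.study_id for r in rec_b]
        for snp in {r.snp_id for r in rec_a}:
            pools = []
            for recs in (rec_a, rec_b):
                ests = [align_to_reference(r, ref, "EAS").estimate
                        for r in recs if r.snp_id == snp]
                ests = [e for e in ests if e is not None]
                if len(ests) >= 2:
                    pools.append(dersimonian_laird_meta(ests).pooled_ae_random)
            if len(pools) == 2:
                assert pools[0] == pytest.approx(pools[1], abs=1e-12)


class TestHwe:
    def test_two_individual_enumeration(self):
        # n=2, n_A=2: P(het=0)=1/3, P(het=2)=2/3; observing 0 -> p=1/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)

    def test_equilibrium_counts_not_rejected(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_extreme_heterozygote_deficit_rejected(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    @pytest.mark.parametrize("counts", [(1, 0, 1), (3, 5, 2), (8, 4, 9), (2, 9, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(brute_hwe_exact(*counts),
                                                        abs=1e-12)

    @pytest.mark.parametrize("counts", [(60, 130, 75), (200, 340, 160),
                                        (90, 160, 80), (150, 60, 150)])
    def test_exact_and_chisq_decisions_agree_for_large_counts(self, counts):
        """Both tests reach the same accept/reject decision at alpha = 0.05 on
        large-count fixtures, and their p-values are close in the rejection
        region.  (Pointwise agreement of the two p-values does not hold in the
        mid range, where the exact test's discrete two-sided tail can sit up
        to ~0.1 above the chi-square approximation.)"""
        p_exact = hwe_exact_test(*counts)
        p_chi = hwe_chisq_test(*counts)
        assert (p_exact < 0.05) == (p_chi < 0.05)
        if p_chi < 0.05:
            assert abs(p_exact - p_chi) < 0.01

    def test_statistics_only_studies_not_testable(self):
        rec = _stat_record("A", "G", 0.2)
        assert hwe_test(rec) is None

    def test_genotype_payload_tested_against_alpha(self):
        rec = StudyRecord(study_id="s", snp_id="rs1", ancestry="Asian",
                          design="case_control", allele_1="A", allele_2="G",
                          genotype_counts=GenotypeCounts(10, 20, 10, 50, 0, 50))
        res = hwe_test(rec)
        assert res.violates and res.p_exact < 0.05


class TestEligibility:
    def _harmonized(self, n, n_excluded=0):
        recs = [_stat_record("A", "G", 0.19) for _ in range(n)]
        out = [align_to_reference(r, _ref(maf=0.20), "EAS") for r in recs[:n - n_excluded]]
        out += [align_to_reference(
            StudyRecord(study_id="x", snp_id="rs1", ancestry="Asian",
                        design="case_control", allele_1="A", allele_2="T",
                        statistics=Statistics(or_value=1.5, p_value=0.01)),
            _ref(minor="A", major="T", maf=0.45), "EAS") for _ in range(n_excluded)]
        return out

    def test_four_studies_eligible(self):
        usable, ok = eligibility_filter(self._harmonized(4))
        assert ok and len(usable) == 4

    def test_three_studies_ineligible(self):
        _, ok = eligibility_filter(self._harmonized(3))
        assert not ok

    def test_exclusions_count_against_eligibility(self):
        usable, ok = eligibility_filter(self._harmonized(5, n_excluded=2))
        assert len(usable) == 3 and not ok
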