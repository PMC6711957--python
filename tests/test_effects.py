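"""Effect extraction: arithmetic values, route selection, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snpmeta.effects import (ExtractionError, effect_from_allele_counts,
                             effect_from_ci, effect_from_pvalue,
                             effect_from_trio, extract_effect,
                             genotype_to_allele_counts, pvalue_denominator,
                             select_data_source)
from snpmeta.records import GenotypeCounts, Statistics, StudyRecord, TrioCounts

counts = st.integers(min_value=0, max_value=5000)


class TestAlleleCountRoute:
    def test_hand_computed_2x2(self):
        # case A/a = 30/70, control A/a = 20/80; effect of allele A
        est = effect_from_allele_counts(30, 70, 20, 80)
        assert est.ae == pytest.approx(math.log((30 * 80) / (70 * 20)), abs=1e-12)
        assert est.ae == pytest.approx(0.5390, abs=1e-4)
        assert est.se_ae == pytest.approx(math.sqrt(1/30 + 1/70 + 1/20 + 1/80), abs=1e-12)
        assert est.se_ae == pytest.approx(0.3318, abs=1e-4)

    def test_symmetric_table_is_null(self):
        est = effect_from_allele_counts(10, 10, 10, 10)
        assert est.ae == 0.0
        assert est.se_ae == pytest.approx(math.sqrt(0.4), abs=1e-12)

    def test_zero_cell_gets_haldane_correction(self):
        est = effect_from_allele_counts(0, 10, 10, 10)
        expected = math.log((0.5 * 10.5) / (10.5 * 10.5))
        assert est.ae == pytest.approx(expected, abs=1e-12)
        assert est.se_ae == pytest.approx(
            math.sqrt(1/0.5 + 3/10.5), abs=1e-12)

    def test_empty_arm_is_an_error(self):
        with pytest.raises(ExtractionError):
            effect_from_allele_counts(0, 0, 10, 10)

    @given(a=st.integers(1, 2000), b=st.integers(1, 2000),
           c=st.integers(1, 2000), d=st.integers(1, 2000))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_under_allele_relabel(self, a, b, c, d):
        fwd = effect_from_allele_counts(a, b, c, d)
        rev = effect_from_allele_counts(b, a, d, c)
        assert rev.ae == pytest.approx(-fwd.ae, abs=1e-12)
        assert rev.se_ae == pytest.approx(fwd.se_ae, abs=1e-12)

    @given(a=st.integers(5, 2000), b=st.integers(5, 2000),
           c=st.integers(5, 2000), d=st.integers(5, 2000))
    @settings(max_examples=50, derandomize=True)
    def test_wald_chi_square_consistency(self, a, b, c, d):
        """(ae/se)^2 equals the Wald chi-square of the 2x2 log OR."""
        est = effect_from_allele_counts(a, b, c, d)
        log_or = math.log(a * d / (b * c))
        var = 1/a + 1/b + 1/c + 1/d
        assert (est.ae / est.se_ae) ** 2 == pytest.approx(log_or**2 / var, rel=1e-12)


class TestGenotypeRoute:
    @pytest.mark.parametrize("geno, expected", [
        ((10, 20, 10, 12, 18, 10), (40, 40, 42, 38)),
        ((0, 0, 0, 1, 1, 1), (0, 0, 3, 3)),
        ((5, 0, 0, 0, 0, 5), (10, 0, 0, 10)),
    ])
    def test_allele_count_collapse(self, geno, expected):
        assert genotype_to_allele_counts(*geno) == expected

    @given(g=st.tuples(*(st.integers(1, 500) for _ in range(6))))
    @settings(max_examples=50, derandomize=True)
    def test_genotype_and_equivalent_allele_payloads_agree(self, g):
        geno_rec = StudyRecord(study_id="s", snp_id="rs1", ancestry="Asian",
                               design="case_control", allele_1="A", allele_2="G",
                               genotype_counts=GenotypeCounts(*g))
        allele_rec = StudyRecord(study_id="s", snp_id="rs1", ancestry="Asian",
                                 design="case_control", allele_1="A", allele_2="G",
                                 allele_counts=GenotypeCounts(*g).to_allele_counts())
        e1, e2 = extract_effect(geno_rec), extract_effect(allele_rec)
        assert e1.ae == pytest.approx(e2.ae, abs=1e-15)
        assert e1.se_ae == pytest.approx(e2.se_ae, abs=1e-15)


class TestPValueRoute:
    def test_back_calculated_se(self):
        est = effect_from_pvalue(1.5, 0.05)
        assert est.ae == pytest.approx(math.log(1.5), abs=1e-12)
        assert est.se_ae == pytest.approx(math.log(1.5) / 1.9566, rel=1e-4)
        est2 = effect_from_pvalue(1.5, 0.01)
        assert est2.se_ae == pytest.approx(math.log(1.5) / 2.5752, rel=1e-4)

    def test_null_or_is_degenerate(self):
        with pytest.raises(ExtractionError):
            effect_from_pvalue(1.0, 0.05)

    def test_protective_or_gives_negative_ae_positive_se(self):
        est = effect_from_pvalue(0.7, 0.01)
        assert est.ae < 0 < est.se_ae

    def test_quantile_approximation_accuracy_profile(self):
        """The closed-form denominator tracks the exact normal quantile:
        within 0.5% for p in [1e-3, 0.2] and never worse than 2.5% across
        [1e-8, 0.5] (the error grows toward both ends of the range)."""
        p = np.logspace(-8, math.log10(0.5), 400)
        approx = np.array([pvalue_denominator(v) for v in p])
        exact = stats.norm.isf(p / 2)
        rel = np.abs(approx / exact - 1)
        assert rel.max() < 0.025
        central = (p >= 1e-3) & (p <= 0.2)
        assert rel[central].max() < 0.005


class TestCiRoute:
    def test_log_scale_width(self):
        est = effect_from_ci(1.18, 1.10, 1.25)
        assert est.se_ae == pytest.approx((math.log(1.25) - math.log(1.10)) / 3.92,
                                          rel=1e-3)
        assert est.se_ae == pytest.approx(0.0326, abs=2e-4)

    def test_symmetric_ci_around_null(self):
        c = 1.4
        est = effect_from_ci(1.0, 1 / c, c)
        assert est.ae == 0.0
        assert est.se_ae == pytest.approx(math.log(c) / 1.96, rel=1e-3)

    def test_misordered_ci_is_an_error(self):
        with pytest.raises(ExtractionError):
            effect_from_ci(1.15, 1.2, 1.1)

    def test_literal_compatibility_mode(self):
        est = effect_from_ci(1.18, 1.10, 1.25, literal=True)
        assert est.se_ae == pytest.approx(1.25 - 1.18, abs=1e-12)


class TestTrioRoute:
    def test_kazeem_farrall_values(self):
        est = effect_from_trio(60, 40)
        assert est.ae == pytest.approx(math.log(1.5), abs=1e-12)
        assert est.se_ae == pytest.approx(math.sqrt(1/60 + 1/40), abs=1e-12)

    def test_balanced_transmission_is_null(self):
        assert effect_from_trio(50, 50).ae == 0.0

    def test_zero_count_corrected(self):
        est = effect_from_trio(0, 10)
        assert est.ae == pytest.approx(math.log(0.5 / 10.5), abs=1e-12)

    def test_literal_se_flag_drops_sqrt(self):
        est = effect_from_trio(60, 40, literal_se=True)
        assert est.se_ae == pytest.approx(1/60 + 1/40, abs=1e-12)


class TestRouteSelection:
    def _rec(self, **payloads):
        return StudyRecord(study_id="s", snp_id="rs1", ancestry="Asian",
                           design=payloads.pop("design", "case_control"),
                           allele_1="A", allele_2="G", **payloads)

    def test_genotype_beats_statistics(self):
        rec = self._rec(genotype_counts=GenotypeCounts(10, 20, 10, 12, 18, 10),
                        statistics=Statistics(or_value=1.5, p_value=0.05))
        assert select_data_source(rec) == "genotype_counts"

    def test_ci_preferred_over_p(self):
        rec = self._rec(statistics=Statistics(or_value=1.5, p_value=0.05,
                                              ci_low=1.1, ci_up=2.1))
        assert select_data_source(rec) == "ci_based"

    def test_p_only_falls_back(self):
        rec = self._rec(statistics=Statistics(or_value=1.5, p_value=0.05))
        assert select_data_source(rec) == "p_based"

    def test_family_design_uses_trio(self):
        rec = self._rec(design="family", trio_counts=TrioCounts(60, 40))
        assert select_data_source(rec) == "trio"
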