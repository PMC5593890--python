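"""The 2x2 engine: Woolf OR, uncorrected chi-square, filters, thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, hypergeom

from hlafinemap.assoc_core import (
    Contingency2x2,
    bonferroni_threshold,
    carrier_association,
    carrier_matrix,
    chi2_2x2,
    common_alleles,
    two_group_table,
    woolf_or,
)
from hlafinemap.genotype_io import AlleleCall, Cohort
from hlafinemap.reported import (
    CLINICAL_SEX_COUNTS,
    HLA_CARRIER_COUNTS,
    table_of,
)

from conftest import make_subject

cells = st.integers(min_value=1, max_value=500)


def fisher_exact_enumerated(t: Contingency2x2) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration (oracle)."""
    n = t.a + t.b + t.c + t.d
    row1, col1 = t.a + t.b, t.a + t.c
    rv = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(t.a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestWoolfOr:
    def test_protective_example(self):
        orci = woolf_or(Contingency2x2(37, 1162, 171, 1024))
        assert round(orci.or_, 2) == 0.19
        assert not orci.corrected

    def test_risk_example_with_ci(self):
        orci = woolf_or(Contingency2x2(283, 917, 179, 1015))
        assert round(orci.or_, 2) == 1.75
        assert orci.ci_low == pytest.approx(1.42, abs=0.02)
        assert orci.ci_high == pytest.approx(2.16, abs=0.02)

    def test_identity_case_symmetric_ci(self):
        orci = woolf_or(Contingency2x2(5, 5, 5, 5))
        assert orci.or_ == pytest.approx(1.0)
        assert math.log(orci.ci_low) == pytest.approx(-math.log(orci.ci_high))

    def test_zero_cell_haldane_flag(self):
        orci = woolf_or(Contingency2x2(0, 10, 5, 5))
        assert orci.corrected
        assert orci.or_ == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_no_exposure_variation_sentinel(self):
        assert not woolf_or(Contingency2x2(0, 10, 0, 10)).defined
        assert not woolf_or(Contingency2x2(10, 0, 10, 0)).defined


class TestChi2:
    def test_strongest_association(self):
        chi = chi2_2x2(Contingency2x2(37, 1162, 171, 1024))
        assert chi.p == pytest.approx(1.9e-22, rel=0.05)

    def test_null_table(self):
        chi = chi2_2x2(Contingency2x2(10, 10, 10, 10))
        assert chi.chi2 == 0
        assert chi.p == 1

    def test_zero_margin_sentinel(self):
        assert not chi2_2x2(Contingency2x2(0, 10, 0, 10)).defined

    def test_against_fisher_oracle(self):
        """Same side of 0.05 and within an order of magnitude of exact p."""
        t = Contingency2x2(8, 113, 169, 753)
        chi = chi2_2x2(t)
        p_exact = fisher_exact_enumerated(t)
        assert (chi.p < 0.05) == (p_exact < 0.05)
        assert abs(math.log10(chi.p) - math.log10(p_exact)) < 1.0

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_closed_form_equals_pearson_sum(self, a, b, c, d):
        """The ad-bc closed form equals the observed-vs-expected sum."""
        t = Contingency2x2(a, b, c, d)
        stat, _, _, expected = chi2_contingency(
            np.array([[a, b], [c, d]]), correction=False
        )
        assert chi2_2x2(t).chi2 == pytest.approx(stat, rel=1e-9)


class TestTableSymmetries:
    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_group_swap_inverts_or_keeps_p(self, a, b, c, d):
        t = Contingency2x2(a, b, c, d)
        s = t.swapped_groups()
        assert woolf_or(s).or_ == pytest.approx(1 / woolf_or(t).or_)
        assert chi2_2x2(s).chi2 == pytest.approx(chi2_2x2(t).chi2)
        assert chi2_2x2(s).p == pytest.approx(chi2_2x2(t).p)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_exposure_swap_inverts_or(self, a, b, c, d):
        t = Contingency2x2(a, b, c, d)
        flipped = Contingency2x2(b, a, d, c)
        assert woolf_or(flipped).or_ == pytest.approx(1 / woolf_or(t).or_)

    def test_equal_enrichment_moves_or_monotonically(self):
        t0 = Contingency2x2(10, 90, 40, 60)
        ors = [
            woolf_or(Contingency2x2(10 + k, 90, 40 + k, 60)).or_
            for k in range(0, 200, 10)
        ]
        diffs = np.diff(ors)
        assert (diffs > 0).all() or (diffs < 0).all()

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_p_in_unit_interval(self, a, b, c, d):
        p = chi2_2x2(Contingency2x2(a, b, c, d)).p
        assert 0 < p <= 1


class TestBonferroni:
    def test_study_configuration(self):
        assert bonferroni_threshold(87) == pytest.approx(5.75e-4, rel=5e-3)

    def test_single_test(self):
        assert bonferroni_threshold(1) == 0.05

    def test_snp_count(self):
        assert bonferroni_threshold(4103) == pytest.approx(0.05 / 4103)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


@pytest.mark.parametrize("allele,entry", sorted(HLA_CARRIER_COUNTS.items()))
def test_published_hla_or_reproduced(allele, entry):
    """Each published carrier OR recomputes to its printed 2 d.p. value."""
    orci = woolf_or(table_of(entry))
    assert round(orci.or_, 2) == entry[4]


@pytest.mark.parametrize("key,entry", sorted(CLINICAL_SEX_COUNTS.items()))
def test_published_clinical_or_reproduced(key, entry):
    """Female-vs-male clinical contrasts recompute to printed ORs."""
    orci = woolf_or(table_of(entry))
    assert round(orci.or_, 2) == entry[4]


class TestCarrierMatrix:
    def test_homozygote_counts_once(self):
        subs = [
            make_subject("1", "case", ("08:03", "08:03")),
            make_subject("2", "case", ("08:03", "04:05")),
            make_subject("3", "case", ("13:02", "14:03")),
        ]
        m = carrier_matrix(Cohort(subjects=subs), "DRB1")
        assert m[AlleleCall("DRB1", "08:03")].case_carriers == 2

    def test_missing_locus_excluded_from_denominator(self, tiny_cohort):
        m = carrier_matrix(tiny_cohort, "DRB1")
        cc = m[AlleleCall("DRB1", "13:02")]
        assert (cc.case_n, cc.control_n) == (3, 2)  # C3 untyped at DRB1

    def test_empty_cohort(self):
        sub = make_subject("1", "case")  # no HLA at all
        assert carrier_matrix(Cohort(subjects=[sub]), "DRB1") == {}


class TestCommonAlleles:
    def _matrix(self, case_c, control_c, n=1000):
        from hlafinemap.assoc_core import CarrierCounts

        return {
            AlleleCall("DRB1", "13:02"): CarrierCounts(case_c, control_c, n, n)
        }

    def test_below_threshold_excluded(self):
        assert common_alleles(self._matrix(9, 9)) == []

    def test_either_group_suffices(self):
        kept = common_alleles(self._matrix(5, 12))
        assert kept == [AlleleCall("DRB1", "13:02")]

    def test_boundary_is_strict(self):
        assert common_alleles(self._matrix(10, 10)) == []  # exactly 1%


class TestCarrierAssociation:
    def test_duplicated_cohort_is_null(self, preset_cohort):
        cohort, _ = preset_cohort
        half = cohort.subjects[:400]
        import copy
        from dataclasses import replace

        dup = [replace(s, id=s.id + "c", phenotype="control") for s in half]
        cases = [replace(s, phenotype="case") for s in half]
        both = Cohort(subjects=cases + dup)
        for r in carrier_association(both, loci=("DRB1", "DQB1")):
            if r.defined:
                assert r.or_ == pytest.approx(1.0)
                assert not r.flags & {"bonferroni_significant", "genome_wide"}

    def test_flags_and_sorting(self, preset_cohort):
        cohort, _ = preset_cohort
        results = carrier_association(cohort, loci=("DRB1", "DQB1"))
        ps = [r.p for r in results if r.defined]
        assert ps == sorted(ps)
        top = results[0]
        assert "bonferroni_significant" in top.flags
        by_factor = {r.factor: r for r in results}
        assert "genome_wide" in by_factor["DQB1*06:04"].flags


class TestTwoGroupTable:
    def test_sex_by_outcome_counts(self):
        subs = []
        # 169/922 affected females, 8/121 affected males, among cases
        for i in range(922):
            subs.append(
                make_subject(
                    f"F{i}", "case", sex="F",
                    clinical={"sjogren": "1" if i < 169 else "0"},
                )
            )
        for i in range(121):
            subs.append(
                make_subject(
                    f"M{i}", "case", sex="M",
                    clinical={"sjogren": "1" if i < 8 else "0"},
                )
            )
        subs.append(make_subject("X", "control", sex="F"))
        t = two_group_table(
            Cohort(subjects=subs),
            split=lambda s: {"F": True, "M": False}.get(s.sex),
            outcome=lambda s: (
                None
                if "sjogren" not in s.clinical
                else s.clinical["sjogren"] == "1"
            ),
            subset=lambda s: s.is_case,
        )
        assert (t.a, t.b, t.c, t.d) == (169, 753, 8, 113)
        assert round(woolf_or(t).or_, 2) == 3.17

    def test_missing_outcome_dropped(self):
        subs = [
            make_subject("1", "case", sex="F", clinical={"x": "1"}),
            make_subject("2", "case", sex="M"),
            make_subject("3", "case", sex="M", clinical={"x": "0"}),
        ]
        t = two_group_table(
            Cohort(subjects=subs),
            split=lambda s: s.sex == "F",
            outcome=lambda s: (
                s.clinical["x"] == "1" if "x" in s.clinical else None
            ),
        )
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_constant_outcome_hits_sentinel_path(self):
        subs = [
            make_subject("1", "case", sex="F", clinical={"x": "0"}),
            make_subject("2", "case", sex="M", clinical={"x": "0"}),
        ]
        t = two_group_table(
            Cohort(subjects=subs),
            split=lambda s: s.sex == "F",
            outcome=lambda s: s.clinical["x"] == "1",
        )
        assert (t.b, t.d) == (1, 1) and (t.a, t.c) == (0, 0)
        assert not woolf_or(t).defined
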