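import pytest

from molemstat import (
    MolemClass,
    assignment_distribution,
    build_reference,
    concordance,
    majority_class,
    melanoma_over_under,
    results_fixture,
)
from molemstat.errors import DataError
from molemstat.schema import SeverityOrder
from molemstat.simulate import HEADLINE_ASSIGNMENT_COUNTS, HEADLINE_TOTAL_DIAGNOSES

C = MolemClass


class TestMajorityClass:
    def test_unique_mode(self):
        assert majority_class([C.I, C.I, C.III]) == (C.I, False)

    def test_bimodal_tie_breaks_toward_severity(self):
        assert majority_class([C.I, C.I, C.III, C.III]) == (C.III, True)

    def test_ii_v_tie_goes_to_v_by_default_risk_order(self):
        assert majority_class([C.II, C.II, C.V, C.V]) == (C.V, True)

    def test_three_way_tie(self):
        # all tied at one rating each; III is the most severe of {I, III, V}
        assert majority_class([C.I, C.III, C.V]) == (C.III, True)

    def test_custom_severity_flips_tie(self):
        order = SeverityOrder({C.I: 1, C.II: 4, C.III: 3, C.IV: 5, C.V: 2})
        assert majority_class([C.II, C.V, C.V, C.II], order) == (C.II, True)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            majority_class([])


class TestBuildReference:
    def test_unanimous(self, unanimous_table):
        ref = build_reference(unanimous_table)
        assert ref.n_ties == 0
        assert ref["U3"] == C.III

    def test_record_order_independent(self, table_from_rows):
        rows = ["L1,P1,I,", "L1,P2,III,", "L1,P3,III,", "L2,P1,V,", "L2,P2,II,"]
        a = build_reference(table_from_rows(rows))
        b = build_reference(table_from_rows(rows[::-1]))
        assert a.majority_of == b.majority_of
        assert a.tie_broken == b.tie_broken


class TestConcordance:
    def test_printed_counts_fixture(self):
        table, ref = results_fixture()
        rep = concordance(table, ref)
        expected = {
            C.I: (600, 677), C.II: (61, 120), C.III: (430, 564),
            C.IV: (88, 114), C.V: (41, 55),
        }
        for cls, (conc, total) in expected.items():
            assert rep.per_class[cls].concordant == conc
            assert rep.per_class[cls].total == total
        assert (rep.overall.count, rep.overall.denominator) == (1220, 1530)
        assert rep.per_class[C.II].overcalled == 29
        assert rep.per_class[C.II].undercalled == 30

    def test_level_discordance_ii_vs_v(self, table_from_rows):
        # class-II majority lesion with one V rating: same mapped value
        t = table_from_rows(["L1,P1,II,", "L1,P2,II,", "L1,P3,V,"])
        rep = concordance(t, build_reference(t))
        pc = rep.per_class[C.II]
        assert (pc.concordant, pc.overcalled, pc.undercalled, pc.level_discordant) \
            == (2, 0, 0, 1)

    def test_unanimous_all_perfect(self, unanimous_table):
        rep = concordance(unanimous_table, build_reference(unanimous_table))
        for pc in rep.per_class.values():
            if pc.total:
                assert pc.rate.value == 1.0
                assert pc.overcalled == pc.undercalled == pc.level_discordant == 0

    def test_partition_exhaustive_and_disjoint(self):
        table, ref = results_fixture()
        rep = concordance(table, ref)
        assert sum(pc.total for pc in rep.per_class.values()) == table.n_records
        for pc in rep.per_class.values():
            assert pc.concordant + pc.overcalled + pc.undercalled \
                + pc.level_discordant == pc.total


class TestMelanomaOverUnder:
    def test_printed_counts(self):
        table, ref = results_fixture()
        over, under = melanoma_over_under(table, ref)
        assert (over.count, over.denominator) == (44, 797)
        assert (under.count, under.denominator) == (123, 678)
        assert round(under.pct, 1) == 18.1

    def test_no_melanoma_reference_undefined(self, table_from_rows):
        t = table_from_rows(["L1,P1,I,", "L1,P2,I,"])
        over, under = melanoma_over_under(t, build_reference(t))
        assert under.value is None
        assert over.value == 0.0

    def test_class_v_in_denominator_never_numerator(self, table_from_rows):
        t = table_from_rows(["L1,P1,III,", "L1,P2,III,", "L1,P3,V,"])
        over, under = melanoma_over_under(t, build_reference(t))
        assert (under.count, under.denominator) == (0, 3)


class TestAssignmentDistribution:
    def test_headline_share(self):
        dist = assignment_distribution(
            HEADLINE_ASSIGNMENT_COUNTS, n_total=HEADLINE_TOTAL_DIAGNOSES
        )
        assert round(dist[C.I].pct, 1) == 44.7
        assert dist[C.I].count == 677

    def test_from_table_sums_to_one(self):
        table, _ = results_fixture()
        dist = assignment_distribution(table=table)
        assert sum(r.value for r in dist.values()) == pytest.approx(1.0)
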