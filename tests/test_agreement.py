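import numpy as np
import pytest

from molemstat import (
    MolemClass,
    agreement_by_reference_class,
    build_reference,
    build_weight_matrix,
    chance_agreement,
    gwet_ac,
    percent_agreement,
    rater_vs_reference_agreement,
    tally,
)
from molemstat.errors import InsufficientDataError
from molemstat.ratings import CountMatrix
from tests._oracle import oracle_gwet
from tests.conftest import random_count_matrix

C = MolemClass
IDENTITY2 = build_weight_matrix("unweighted", [1, 2])
MOLEM_W = build_weight_matrix("quadratic")


def cm(rows, q=5):
    return CountMatrix(tuple(f"L{i}" for i in range(len(rows))),
                       np.asarray(rows), categories=tuple(range(q)))


class TestHandDerivedValues:
    """Four 2-rater items (A,A),(A,A),(B,B),(A,B), worked by hand."""

    FOUR = [[2, 0], [2, 0], [0, 2], [1, 1]]

    def test_percent_agreement(self):
        assert percent_agreement(cm(self.FOUR, 2), IDENTITY2) == pytest.approx(0.75)

    def test_chance_agreement(self):
        assert chance_agreement(cm(self.FOUR, 2), IDENTITY2) == pytest.approx(0.46875)

    def test_coefficient(self):
        res = gwet_ac(cm(self.FOUR, 2), IDENTITY2)
        assert res.coefficient == pytest.approx((0.75 - 0.46875) / (1 - 0.46875))

    def test_uniform_prevalence_closed_form(self):
        # one rating in each category per item -> pi uniform over 5 classes
        rows = [np.eye(5, dtype=int)[k] * 2 for k in range(5)]
        w5 = build_weight_matrix("unweighted")
        assert chance_agreement(cm(rows), w5) == pytest.approx(0.2)


class TestWeightedPairs:
    def test_i_v_pair_partial_credit(self):
        counts = cm([[1, 0, 0, 0, 1], [2, 0, 0, 0, 0]])
        assert percent_agreement(counts, MOLEM_W) == pytest.approx((8 / 9 + 1) / 2)

    def test_ii_v_pair_full_credit(self):
        counts = cm([[0, 1, 0, 0, 1]])
        assert percent_agreement(counts, MOLEM_W) == pytest.approx(1.0)


class TestDegenerateInputs:
    def test_no_multirated_item_rejected(self):
        with pytest.raises(InsufficientDataError):
            percent_agreement(cm([[1, 0, 0, 0, 0]]), MOLEM_W)

    def test_single_category_chance_zero_identity(self):
        counts = cm([[3, 0, 0, 0, 0], [2, 0, 0, 0, 0]])
        w5 = build_weight_matrix("unweighted")
        assert chance_agreement(counts, w5) == pytest.approx(0.0)

    def test_perfect_agreement(self, unanimous_table):
        res = gwet_ac(tally(unanimous_table), MOLEM_W)
        assert res.coefficient == pytest.approx(1.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.band == "almost perfect"

    def test_single_agreement_item_has_no_ci(self):
        res = gwet_ac(cm([[2, 1, 0, 0, 0], [1, 0, 0, 0, 0]]), MOLEM_W)
        assert res.se is None and res.ci_low is None


class TestOracleEquivalence:
    """Vectorized path vs the loop-based reference, random small tables."""

    @pytest.mark.parametrize("scheme", ["unweighted", "quadratic"])
    def test_random_tables(self, scheme):
        rng = np.random.default_rng(20240917)
        w = build_weight_matrix(scheme)
        wl = w.w.tolist()
        for _ in range(60):
            counts = random_count_matrix(rng)
            pa, pe, ac = oracle_gwet(counts.r.tolist(), wl)
            res = gwet_ac(counts, w, variance="none")
            assert res.percent_agreement == pytest.approx(pa, abs=1e-10)
            assert res.chance_agreement == pytest.approx(pe, abs=1e-10)
            assert res.coefficient == pytest.approx(ac, abs=1e-10)


class TestInvariants:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        counts = random_count_matrix(rng)
        perm = rng.permutation(counts.n_lesions)
        shuffled = CountMatrix(tuple(f"X{i}" for i in range(counts.n_lesions)),
                               counts.r[perm], counts.categories)
        a = gwet_ac(counts, MOLEM_W, variance="none")
        b = gwet_ac(shuffled, MOLEM_W, variance="none")
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-14)

    def test_identity_two_raters_is_concordant_pair_fraction(self):
        rng = np.random.default_rng(9)
        w5 = build_weight_matrix("unweighted")
        rows = []
        for _ in range(40):
            k, l = rng.integers(0, 5, size=2)
            row = np.zeros(5, dtype=int)
            row[k] += 1
            row[l] += 1
            rows.append(row)
        frac = np.mean([r.max() == 2 for r in rows])
        assert percent_agreement(cm(rows), w5) == pytest.approx(frac)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(11)
        widths = []
        for n in (50, 200, 800):
            rows = []
            for _ in range(n):
                row = np.zeros(5, dtype=int)
                true = rng.integers(0, 5)
                for _ in range(5):
                    k = true if rng.random() < 0.8 else rng.integers(0, 5)
                    row[k] += 1
                rows.append(row)
            res = gwet_ac(cm(rows), MOLEM_W)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_jackknife_and_bootstrap_agree_roughly(self):
        rng = np.random.default_rng(5)
        counts = random_count_matrix(rng, max_lesions=30)
        jk = gwet_ac(counts, MOLEM_W, variance="jackknife")
        bs = gwet_ac(counts, MOLEM_W, variance="bootstrap", seed=1, n_boot=500)
        assert bs.se == pytest.approx(jk.se, rel=0.5)


class TestReferenceComparisons:
    def test_all_match_reference_gives_one(self, unanimous_table):
        ref = build_reference(unanimous_table)
        res = rater_vs_reference_agreement(unanimous_table, ref.majority_of, MOLEM_W)
        assert res.coefficient == pytest.approx(1.0)

    def test_weighting_credits_near_misses(self, table_from_rows):
        rows = []
        for i in range(12):
            rows += [f"L{i},P1,III,", f"L{i},P2,III,", f"L{i},P3,III,"]
        for i in range(12):  # a one-step miss per lesion
            rows += [f"L{12+i},P1,III,", f"L{12+i},P2,III,", f"L{12+i},P3,IV,"]
        table = table_from_rows(rows)
        ref = build_reference(table)
        res = rater_vs_reference_agreement(table, ref.majority_of, MOLEM_W)
        raw = np.mean([
            cls == ref.majority_of[lid]
            for lid, cls in zip(table.df["lesion_id"], table.df["molem_class"])
        ])
        assert res.percent_agreement > raw

    def test_by_class_unanimous(self, unanimous_table):
        counts = tally(unanimous_table)
        ref = build_reference(unanimous_table)
        per = agreement_by_reference_class(counts, MOLEM_W, ref.majority_of)
        assert set(per) == {C.I, C.II, C.III, C.IV, C.V}
        for res in per.values():
            assert res.coefficient == pytest.approx(1.0)

    def test_single_lesion_stratum_flagged_no_ci(self, unanimous_table):
        counts = tally(unanimous_table)
        ref = build_reference(unanimous_table)
        per = agreement_by_reference_class(counts, MOLEM_W, ref.majority_of)
        assert per[C.V].se is None  # only one class-V lesion
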