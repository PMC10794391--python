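"""Voting combiners, product-rule and empirical combination, independence."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from screenplan.combiner import (
    Combiner,
    DependenceError,
    Procedure,
    combine,
    combine_empirical,
    combine_independent,
    conditional_independence_test,
    enumerate_combiners,
    enumerate_procedures,
    get_combiner,
    vote,
)
from screenplan.metrics import Accuracy, InputError, accuracy_from_responses
from screenplan.simulate import CohortSpec, simulate_cohort
from screenplan.simulate import TestSpec as TrialProbs

# independent logical definitions of the 18 rules, used as the oracle for
# both the weight rule's truth table and the product-rule combination
LOGIC = {
    1: lambda a, b, c: a,
    2: lambda a, b, c: b,
    3: lambda a, b, c: c,
    4: lambda a, b, c: a and b,
    5: lambda a, b, c: a and c,
    6: lambda a, b, c: b and c,
    7: lambda a, b, c: a or b,
    8: lambda a, b, c: a or c,
    9: lambda a, b, c: b or c,
    10: lambda a, b, c: a or b or c,
    11: lambda a, b, c: a + b + c >= 2,
    12: lambda a, b, c: a and b and c,
    13: lambda a, b, c: (a or b) and c,
    14: lambda a, b, c: (a or c) and b,
    15: lambda a, b, c: (b or c) and a,
    16: lambda a, b, c: (a and b) or c,
    17: lambda a, b, c: (a and c) or b,
    18: lambda a, b, c: (b and c) or a,
}


def _oracle_combined(chars, ek):
    """Exhaustive outcome-tuple summation using the logical rule only."""
    sen = spe = 0.0
    for a, b, c in itertools.product((0, 1), repeat=3):
        p_hp = p_ls = 1.0
        for t, o in zip("ABC", (a, b, c)):
            if t in chars:
                p_hp *= chars[t].sen if o else 1 - chars[t].sen
                p_ls *= (1 - chars[t].spe) if o else chars[t].spe
        if bool(LOGIC[ek](a, b, c)):
            sen += p_hp
        else:
            spe += p_ls
    # uninvolved tests marginalize out: their outcome probabilities sum to 1
    return sen, spe


class TestCatalogue:
    def test_exactly_18_combiners(self):
        combiners = enumerate_combiners()
        assert len(combiners) == 18
        assert sorted(c.ek for c in combiners) == list(range(1, 19))

    def test_anchored_evaluation_keys(self):
        assert get_combiner(11).label == "at least two times headphones"
        assert get_combiner(11).weights == (0.5, 0.5, 0.5)
        assert get_combiner(12).label == "Test A AND Test B AND Test C"
        assert get_combiner(13).label == "(Test A OR Test B) AND Test C"
        w = get_combiner(13).weights
        assert [float(x) for x in w] == [0.25, 0.25, 0.75]
        assert get_combiner(6).label == "Test B AND Test C"

    @pytest.mark.parametrize("ek", sorted(LOGIC))
    def test_weight_rule_matches_logical_truth_table(self, ek):
        comb = get_combiner(ek)
        for outcomes in itertools.product((0, 1), repeat=3):
            assert vote(comb, outcomes) == int(bool(LOGIC[ek](*outcomes)))

    def test_vote_examples(self):
        maj = get_combiner(11)
        assert vote(maj, (1, 1, 0)) == 1
        assert vote(maj, (1, 0, 0)) == 0

    def test_remapping_is_injective_and_applied(self):
        remapped = enumerate_combiners(ek_map={11: 101})
        assert {c.ek for c in remapped} == (set(range(1, 19)) - {11}) | {101}
        with pytest.raises(InputError):
            enumerate_combiners(ek_map={1: 5, 2: 5})

    def test_degenerate_weights_rejected(self):
        from fractions import Fraction

        with pytest.raises(InputError):
            Combiner(ek=99, weights=(Fraction(1, 4), Fraction(1, 4), Fraction(1, 4)),
                     label="never positive")


class TestProcedures:
    @pytest.mark.parametrize("t, expected", [(6, 2178), (1, 18), (2, 102)])
    def test_counts(self, t, expected):
        procs = enumerate_procedures(t)
        assert len(procs) == expected
        assert len({p.spec for p in procs}) == expected

    def test_count_formula(self):
        for t in (1, 2, 3, 6):
            assert len(enumerate_procedures(t)) == 3 * t + 6 * t**2 + 9 * t**3

    def test_thresholds_only_for_involved_tests(self):
        with pytest.raises(InputError):
            Procedure(get_combiner(1), {"A": 1, "B": 2})
        p = Procedure(get_combiner(6), {"B": 3, "C": 5})
        assert p.spec == "EK6:B3,C5"


def _chars(sens, spes):
    return {
        t: Accuracy(sen=s, spe=p, n_pos=80, n_neg=131)
        for t, s, p in zip("ABC", sens, spes)
    }


class TestCombineIndependent:
    def test_pairwise_and_or_closed_forms(self):
        chars = _chars((0.9, 0.8, 0.7), (0.6, 0.7, 0.8))
        both = combine_independent(chars, get_combiner(4))  # A AND B
        assert both.sen == pytest.approx(0.9 * 0.8)
        assert both.spe == pytest.approx(1 - (1 - 0.6) * (1 - 0.7))
        either = combine_independent(chars, get_combiner(7))  # A OR B
        assert either.sen == pytest.approx(1 - 0.1 * 0.2)
        assert either.spe == pytest.approx(0.6 * 0.7)

    def test_majority_matches_exhaustive_oracle(self):
        chars = _chars((0.8, 0.8, 0.8), (0.9, 0.9, 0.9))
        got = combine_independent(chars, get_combiner(11))
        sen, spe = _oracle_combined(chars, 11)
        assert got.sen == pytest.approx(sen)
        assert got.spe == pytest.approx(spe)

    @pytest.mark.parametrize("ek", sorted(LOGIC))
    def test_all_combiners_match_oracle_random_characteristics(self, ek, rng):
        for _ in range(10):
            chars = _chars(rng.uniform(0.05, 0.99, 3), rng.uniform(0.05, 0.99, 3))
            got = combine_independent(chars, get_combiner(ek))
            sen, spe = _oracle_combined(chars, ek)
            assert got.sen == pytest.approx(sen, abs=1e-12)
            assert got.spe == pytest.approx(spe, abs=1e-12)

    def test_outcome_probabilities_sum_to_one(self, rng):
        chars = _chars(rng.uniform(0, 1, 3), rng.uniform(0, 1, 3))
        for ek in (4, 11, 13):
            res = combine_independent(chars, get_combiner(ek))
            for device, probs in res.outcome_probs.items():
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    @given(
        sa=st.floats(0, 1), sb=st.floats(0, 1),
        pa=st.floats(0, 1), pb=st.floats(0, 1),
    )
    def test_and_or_bounds(self, sa, sb, pa, pb):
        chars = _chars((sa, sb, 0.5), (pa, pb, 0.5))
        both = combine_independent(chars, get_combiner(4))
        either = combine_independent(chars, get_combiner(7))
        eps = 1e-9
        assert both.sen <= min(sa, sb) + eps and both.spe >= max(pa, pb) - eps
        assert either.sen >= max(sa, sb) - eps and either.spe <= min(pa, pb) + eps


class TestCombineEmpirical:
    def test_perfect_cohort(self):
        spec = CohortSpec(
            n_participants=400, pi=0.5,
            tests={t: TrialProbs(1.0, 0.0) for t in "ABC"}, seed=3,
        )
        frame = simulate_cohort(spec).frame
        proc = Procedure(get_combiner(11), {"A": 4, "B": 4, "C": 4})
        res = combine_empirical(frame, proc)
        assert res.sen == 1.0 and res.spe == 1.0

    def test_single_test_procedure_equals_accuracy_from_responses(self):
        spec = CohortSpec(n_participants=500, pi=0.4, seed=11)
        frame = simulate_cohort(spec).frame
        proc = Procedure(get_combiner(2), {"B": 3})
        res = combine_empirical(frame, proc)
        acc = accuracy_from_responses(frame, "B", 3)
        assert res.sen == acc.sen and res.spe == acc.spe

    def test_converges_to_product_rule_on_independent_cohort(self, large_independent_cohort):
        from screenplan.simulate import theoretical_accuracy

        spec, cohort = large_independent_cohort
        proc = Procedure(get_combiner(11), {"A": 5, "B": 5, "C": 6})
        chars = {
            t: Accuracy(
                sen=theoretical_accuracy(spec.tests[t].q_pos, 6, proc.thresholds[t]),
                spe=1 - theoretical_accuracy(spec.tests[t].q_neg, 6, proc.thresholds[t]),
                n_pos=1, n_neg=1,
            )
            for t in "ABC"
        }
        expected = combine_independent(chars, proc.combiner)
        got = combine_empirical(cohort.frame, proc)
        n_group = 10_000
        for e, g in ((expected.sen, got.sen), (expected.spe, got.spe)):
            se = np.sqrt(e * (1 - e) / n_group)
            assert abs(e - g) < 3.5 * se

    def test_dependent_cohort_departs_from_product_rule(self):
        """Shared-error responders push the ensemble away from independence."""
        from screenplan.simulate import theoretical_accuracy

        spec = CohortSpec(
            n_participants=20_000, pi=0.5, dependence=0.8, seed=5,
        )
        frame = simulate_cohort(spec).frame
        proc = Procedure(get_combiner(12), {"A": 6, "B": 6, "C": 6})
        chars = {
            t: Accuracy(
                sen=accuracy_from_responses(frame, t, 6).sen,
                spe=accuracy_from_responses(frame, t, 6).spe,
                n_pos=1, n_neg=1,
            )
            for t in "ABC"
        }
        product = combine_independent(chars, proc.combiner)
        empirical = combine_empirical(frame, proc)
        se = np.sqrt(product.sen * (1 - product.sen) / 10_000)
        assert abs(product.sen - empirical.sen) > 3 * se


class TestConditionalIndependence:
    @staticmethod
    def _cohort_from_table(table, device="headphones"):
        """Build a one-trial-per-test cohort realizing a 2×2 (A+, A−) × (B+, B−) table."""
        import pandas as pd

        rows = []
        for (a, b), count in zip(((1, 1), (1, 0), (0, 1), (0, 0)), table):
            rows += [{"device": device, "testA_1": a, "testB_1": b}] * count
        return pd.DataFrame(rows)

    def test_product_structured_table_not_rejected(self):
        frame = self._cohort_from_table([40, 10, 40, 10])
        res = conditional_independence_test(
            frame, "A", "B", {"A": 1, "B": 1}, "headphones"
        )
        assert res.p_value > 0.9
        assert not res.rejected

    def test_diagonal_table_rejected(self):
        frame = self._cohort_from_table([50, 0, 0, 50])
        res = conditional_independence_test(
            frame, "A", "B", {"A": 1, "B": 1}, "headphones"
        )
        assert res.method == "chi2"
        assert res.p_value < 1e-6 and res.rejected

    def test_small_expected_counts_use_exact_test(self):
        frame = self._cohort_from_table([6, 1, 1, 6])
        res = conditional_independence_test(
            frame, "A", "B", {"A": 1, "B": 1}, "headphones"
        )
        assert res.method == "exact-multinomial"
        assert 0.0 <= res.p_value <= 1.0

    def test_exact_test_matches_direct_enumeration(self):
        """Exact multinomial p-value agrees with a brute-force enumeration."""
        from itertools import product as iproduct

        from scipy.stats import multinomial

        table = [5, 2, 3, 4]
        n = sum(table)
        row1 = (table[0] + table[1]) / n
        col1 = (table[0] + table[2]) / n
        p = [row1 * col1, row1 * (1 - col1), (1 - row1) * col1, (1 - row1) * (1 - col1)]
        p_obs = multinomial.pmf(table, n, p)
        total = 0.0
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    q = multinomial.pmf([a, b, c, d], n, p)
                    if q <= p_obs * (1 + 1e-9):
                        total += q
        frame = self._cohort_from_table(table)
        res = conditional_independence_test(
            frame, "A", "B", {"A": 1, "B": 1}, "headphones"
        )
        assert res.p_value == pytest.approx(total, rel=1e-8)

    def test_degenerate_margin_flagged(self):
        frame = self._cohort_from_table([10, 10, 0, 0])  # B margin constant
        res = conditional_independence_test(
            frame, "A", "B", {"A": 1, "B": 1}, "headphones"
        )
        assert res.degenerate and not res.rejected

    def test_empty_stratum_rejected(self):
        frame = self._cohort_from_table([5, 5, 5, 5])
        with pytest.raises(InputError):
            conditional_independence_test(
                frame, "A", "B", {"A": 1, "B": 1}, "loudspeakers"
            )

    def test_rejection_rate_near_alpha_on_independent_cohorts(self):
        """Under conditional independence the test rejects at ≈ α = .10."""
        rejections = 0
        replicates = 400
        for r in range(replicates):
            spec = CohortSpec(n_participants=300, pi=1.0, seed=100_000 + r)
            frame = simulate_cohort(spec).frame
            res = conditional_independence_test(
                frame, "A", "B", {"A": 6, "B": 6}, "headphones"
            )
            rejections += res.rejected
        rate = rejections / replicates
        se = np.sqrt(0.1 * 0.9 / replicates)
        assert abs(rate - 0.10) < 4 * se


class TestCombineGuard:
    def test_refuses_product_rule_without_any_input(self):
        proc = Procedure(get_combiner(4), {"A": 1, "B": 1})
        with pytest.raises(InputError):
            combine(proc)

    def test_falls_back_to_empirical_when_dependence_detected(self):
        spec = CohortSpec(n_participants=4000, pi=0.5, dependence=0.9, seed=21)
        frame = simulate_cohort(spec).frame
        proc = Procedure(get_combiner(4), {"A": 6, "B": 6})
        chars = {
            t: Accuracy(sen=0.8, spe=0.8, n_pos=1, n_neg=1) for t in "AB"
        }
        res = combine(proc, chars=chars, responses=frame)
        assert res.method == "empirical"

    def test_raises_on_dependence_when_asked(self):
        spec = CohortSpec(n_participants=4000, pi=0.5, dependence=0.9, seed=21)
        frame = simulate_cohort(spec).frame
        proc = Procedure(get_combiner(4), {"A": 6, "B": 6})
        chars = {t: Accuracy(sen=0.8, spe=0.8, n_pos=1, n_neg=1) for t in "AB"}
        with pytest.raises(DependenceError):
            combine(proc, chars=chars, responses=frame, on_dependence="raise")

    def test_product_rule_used_when_independent(self):
        spec = CohortSpec(n_participants=2000, pi=0.5, dependence=0.0, seed=22)
        frame = simulate_cohort(spec).frame
        proc = Procedure(get_combiner(4), {"A": 4, "B": 4})
        chars = {t: Accuracy(sen=0.8, spe=0.8, n_pos=1, n_neg=1) for t in "AB"}
        res = combine(proc, chars=chars, responses=frame)
        # with α=.10 a false rejection is possible but unlikely for this seed
        assert res.method == "independent-product"
        assert res.sen == pytest.approx(0.64)
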