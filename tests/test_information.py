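"""Mutual information, independence tests and entropy profiles."""

import math

import numpy as np
import pytest

from symdyn import (Alphabet, SymbolSequence, block_entropy,
                    compare_mi_profiles, conditional_entropy, entropy_limit,
                    entropy_profile, good_statistics_check, mutual_information,
                    pair_independence_test, shifted_self_information)
from symdyn.information import MIProfile

from conftest import make_seq


def brute_force_mi(pairs):
    """Plug-in MI by direct cell summation over an explicit pair list."""
    from collections import Counter
    n = len(pairs)
    joint = Counter(pairs)
    pa = Counter(a for a, _ in pairs)
    pb = Counter(b for _, b in pairs)
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        total += p_ab * math.log2(p_ab / ((pa[a] / n) * (pb[b] / n)))
    return total


class TestMutualInformation:
    def test_self_information_equals_order_one_entropy(self, session):
        assert mutual_information(session, session) == \
            pytest.approx(block_entropy(session, 1))

    def test_independent_product_form_gives_zero(self):
        a = make_seq("aabb" * 4)
        b = make_seq("abab" * 4)  # every (i, j) cell holds count 4
        assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_explicit_joint(self):
        # joint counts {(0,0): 2, (0,1): 1, (1,0): 1, (1,1): 2}
        a = make_seq("001011")
        b = make_seq("000111")
        pairs = list(zip(a.tokens, b.tokens))
        assert mutual_information(a, b) == pytest.approx(brute_force_mi(pairs))

    def test_symmetry(self, session):
        other = SymbolSequence(session.tokens[::-1], session.alphabet)
        assert mutual_information(session, other) == \
            pytest.approx(mutual_information(other, session), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(make_seq("ab"), make_seq("abc"))


class TestShiftedSelfInformation:
    def test_zero_shift_is_entropy(self, session):
        prof = shifted_self_information(session, 5)
        assert prof.values[0] == pytest.approx(block_entropy(session, 1))

    def test_period_two_sequence_fully_predictable(self):
        prof = shifted_self_information(make_seq("AB" * 100), 4)
        assert prof.values[2] == pytest.approx(1.0, abs=1e-9)
        assert prof.values[4] == pytest.approx(1.0, abs=1e-9)

    def test_iid_sequence_decorrelates(self):
        rng = np.random.default_rng(1)
        seq = SymbolSequence(tuple(str(b) for b in rng.integers(0, 2, 10_000)))
        prof = shifted_self_information(seq, 5)
        assert prof.values[1:].max() < 0.01

    def test_k_max_bound(self):
        with pytest.raises(ValueError):
            shifted_self_information(make_seq("ab"), 2)


class TestIndependenceTest:
    def test_observed_equal_expected_gives_zero(self):
        # "aabb" at shift 2 yields only (a, b) pairs: the table's own margins
        # reproduce it exactly, so chi2 = 0 and p = 1
        chi2, _, p = pair_independence_test(make_seq("aabb"), 2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_deterministic_pairing_rejected(self):
        # shift 2 on a period-2 message pairs each symbol with itself
        _, _, p = pair_independence_test(make_seq("ab" * 32), 2)
        assert p < 1e-6

    def test_zero_shift_rejected_for_nonconstant(self, session):
        chi2, dof, p = pair_independence_test(session, 0)
        assert p < 1e-10

    def test_dof_uses_declared_alphabet(self, session):
        _, dof, _ = pair_independence_test(session, 1)
        assert dof == 441  # (22 - 1)^2

    def test_markov_chain_structure_detected_then_mixes(self):
        from symdyn.datasets import dialog_alphabet, dialog_transition_matrix
        from symdyn.sequences import generate_markov_dialog
        seq = generate_markov_dialog(dialog_transition_matrix(0.4),
                                     dialog_alphabet(), 20_000, seed=5)
        _, _, p1 = pair_independence_test(seq, 1)
        assert p1 < 1e-6  # first-order memory
        prof = shifted_self_information(seq, 6)
        assert prof.values[1] > prof.values[3] > prof.values[6] - 0.05


class TestEntropies:
    def test_constant_sequence_zero(self, constant_seq):
        for n in (1, 2, 5):
            assert block_entropy(constant_seq, n) == 0.0

    def test_iid_binary_near_one_bit(self):
        rng = np.random.default_rng(2)
        seq = SymbolSequence(tuple(str(b) for b in rng.integers(0, 2, 100_000)))
        assert block_entropy(seq, 1) == pytest.approx(1.0, abs=0.01)

    def test_all_unique_words_hit_counting_bound(self):
        # 317 distinct tokens: every 5-word is distinct, H_5 = log2(313)
        seq = SymbolSequence(tuple(f"t{i}" for i in range(317)))
        assert block_entropy(seq, 5) == pytest.approx(math.log2(313))

    def test_profile_monotonicity_with_good_statistics(self, random_binary_seq):
        prof = entropy_profile(random_binary_seq, n_max=5)
        assert all(prof.good_statistics)
        assert np.all(np.diff(prof.H) >= -1e-12)
        assert np.all(np.diff(prof.h) <= 1e-12)

    def test_conditional_entropy_identities(self, random_binary_seq):
        prof = entropy_profile(random_binary_seq, n_max=4)
        assert conditional_entropy(prof, 0) == pytest.approx(prof.H[0])
        assert conditional_entropy(prof, 2) == \
            pytest.approx(block_entropy(random_binary_seq, 3) -
                          block_entropy(random_binary_seq, 2))

    def test_period_two_next_symbol_determined(self):
        # plug-in h_1 is zero up to the O(1/L) edge effect of the differing
        # window denominators
        prof = entropy_profile(make_seq("AB" * 200), n_max=3)
        assert conditional_entropy(prof, 1) == pytest.approx(0.0, abs=1e-3)

    def test_entropy_bounded_by_window_count(self, session):
        for n in (1, 3, 5):
            assert block_entropy(session, n) <= math.log2(len(session) - n + 1) + 1e-12


class TestGoodStatistics:
    @pytest.mark.parametrize("L, n_alpha, n, expected, flag", [
        (317, 22, 1, 14.4, True),
        (317, 22, 2, 0.65, False),
        (1000, 2, 5, 31.1, True),
        (10, 2, 10, 1 / 1024, False),
    ])
    def test_expected_counts(self, L, n_alpha, n, expected, flag):
        count, ok = good_statistics_check(L, n_alpha, n)
        assert count == pytest.approx(expected, rel=0.01)
        assert ok is flag


class TestEntropyLimit:
    @pytest.mark.parametrize("L, expected", [(317, 8.308), (1, 0.0), (1024, 10.0)])
    def test_values(self, L, expected):
        assert entropy_limit(L) == pytest.approx(expected, abs=5e-4)

    def test_session_scale_limits(self):
        assert [round(entropy_limit(L), 3) for L in (317, 549, 713)] == \
            [8.308, 9.101, 9.478]


class TestCompareProfiles:
    @staticmethod
    def _profile(values):
        values = np.asarray(values, float)
        k = np.arange(len(values))
        return MIProfile(shifts=k, values=values, chi2=np.zeros_like(values),
                         dof=1, p_values=np.ones_like(values))

    def test_identical_profiles_degenerate(self):
        p = self._profile(np.linspace(2, 0, 25))
        res = compare_mi_profiles(p, p)
        assert res.degenerate and res.t is None

    def test_offset_profiles_strongly_significant(self):
        rng = np.random.default_rng(0)
        base = np.linspace(2, 0.2, 25)
        a = self._profile(base + 0.3 + rng.normal(0, 0.02, 25))
        b = self._profile(base + rng.normal(0, 0.02, 25))
        res = compare_mi_profiles(a, b, range(25))
        assert res.p < 0.001

    def test_null_differences_give_uniform_p(self):
        rng = np.random.default_rng(7)
        ps = []
        base = np.linspace(2, 0.2, 25)
        for _ in range(200):
            a = self._profile(base + rng.normal(0, 0.05, 25))
            b = self._profile(base + rng.normal(0, 0.05, 25))
            ps.append(compare_mi_profiles(a, b).p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_range_validation(self):
        a = self._profile(np.linspace(2, 0, 10))
        b = self._profile(np.linspace(2, 0, 5))
        with pytest.raises(ValueError):
            compare_mi_profiles(a, b, range(10))
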