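"""Surrogate construction, normalization and Monte Carlo null tests."""

import itertools

import numpy as np
import pytest

from symdyn import (Alphabet, SymbolSequence, barnard_hope_reject,
                    complexity_generation_rate, equiprobable_surrogate,
                    estimate_transition_matrix, grammar_complexity,
                    lz_complexity, markov_surrogate, monte_carlo_pnull,
                    normalized_complexity, quarter_profile, shuffle_surrogate,
                    symbol_frequencies)
from symdyn.datasets import dialog_alphabet, dialog_transition_matrix
from symdyn.sequences import generate_markov_dialog

from conftest import make_seq


class TestTransitionMatrix:
    def test_simple_counts(self):
        tm = estimate_transition_matrix(make_seq("ABAB"))
        assert tm.probability("A", "B") == 1.0
        assert tm.probability("B", "A") == 1.0
        idx = tm.alphabet.index()
        assert tm.counts[idx["A"], idx["B"]] == 2
        assert tm.counts[idx["B"], idx["A"]] == 1

    def test_constant(self):
        tm = estimate_transition_matrix(make_seq("AAAA"))
        assert tm.probability("A", "A") == 1.0

    def test_row_counts_match_symbol_occurrences(self, session):
        tm = estimate_transition_matrix(session)
        idx = session.alphabet.index()
        heads = session.tokens[:-1]
        for s in set(heads):
            assert tm.counts[idx[s]].sum() == heads.count(s)

    def test_parameter_recovery_binary_chain(self):
        # each row visited ~L/2 times: elementwise recovery to 0.01
        alpha = Alphabet("AB")
        T = np.array([[0.7, 0.3], [0.4, 0.6]])
        seq = generate_markov_dialog(T, alpha, 100_000, seed=3)
        est = estimate_transition_matrix(seq).probabilities
        assert np.abs(est - T).max() < 0.01

    def test_parameter_recovery_22_states_within_binomial_bounds(self):
        # per-cell error within 5 binomial SDs of the row occupancy
        n = 22
        alpha = Alphabet([chr(65 + i) for i in range(n)])
        T = 0.2 * np.eye(n) + 0.8 / n * np.ones((n, n))
        seq = generate_markov_dialog(T, alpha, 100_000, seed=3)
        tm = estimate_transition_matrix(seq)
        visits = tm.counts.sum(axis=1, keepdims=True)
        sd = np.sqrt(T * (1 - T) / visits)
        assert np.all(np.abs(tm.probabilities - T) < 5 * sd)

    def test_parameter_recovery_dialog_chain_well_visited_rows(self):
        # rows of rare codes are visited too few times for tight elementwise
        # recovery; restrict the bound to rows with adequate occupancy
        alpha = dialog_alphabet()
        T = dialog_transition_matrix()
        seq = generate_markov_dialog(T, alpha, 100_000, seed=3)
        tm = estimate_transition_matrix(seq)
        rows = np.where(tm.counts.sum(axis=1) >= 3000)[0]
        assert rows.size >= 10
        assert np.abs(tm.probabilities[rows] - T[rows]).max() < 0.02


class TestEquiprobableSurrogate:
    def test_length_and_alphabet(self):
        alpha = Alphabet("abc")
        s = equiprobable_surrogate(7, alpha, seed=0)
        assert len(s) == 7 and set(s.tokens) <= set("abc")

    def test_singleton_alphabet(self):
        s = equiprobable_surrogate(5, Alphabet("x"), seed=0)
        assert s.tokens == ("x",) * 5

    def test_frequencies_within_binomial_bound(self):
        alpha = dialog_alphabet()
        s = equiprobable_surrogate(100_000, alpha, seed=1)
        t = symbol_frequencies(s)
        p = 1 / 22
        sd = np.sqrt(p * (1 - p) / 100_000)
        for sym in alpha.symbols:
            assert abs(t.frequency((sym,)) - p) < 5 * sd


class TestMarkovSurrogate:
    def test_unique_witness_reproduced(self):
        seq = make_seq("ABAB")
        for seed in range(5):
            assert markov_surrogate(seq, seed).tokens == seq.tokens

    def test_pair_counts_preserved_exactly(self):
        rng = np.random.default_rng(0)
        for trial in range(1000):
            n_alpha = int(rng.integers(2, 6))
            L = int(rng.integers(2, 60))
            symbols = [chr(97 + i) for i in range(n_alpha)]
            seq = SymbolSequence(tuple(rng.choice(symbols, size=L)))
            surr = markov_surrogate(seq, seed=int(rng.integers(0, 2**31 - 1)))
            assert len(surr) == len(seq)
            assert surr.tokens[0] == seq.tokens[0]
            a = estimate_transition_matrix(seq).counts if L >= 2 else None
            b = estimate_transition_matrix(surr).counts
            assert np.array_equal(a, b)

    def test_randomization_produces_distinct_surrogates(self):
        seq = make_seq("AABBA")
        seen = {markov_surrogate(seq, seed).tokens for seed in range(40)}
        assert len(seen) >= 2
        # every observed surrogate is a genuine Eulerian rearrangement
        ref = estimate_transition_matrix(seq).counts
        for toks in seen:
            got = estimate_transition_matrix(SymbolSequence(toks, seq.alphabet)).counts
            assert np.array_equal(ref, got)


class TestShuffleSurrogate:
    def test_constant_invariant(self):
        seq = make_seq("aaaa")
        assert shuffle_surrogate(seq, 3).tokens == seq.tokens

    def test_symbol_counts_preserved(self, session):
        surr = shuffle_surrogate(session, 9)
        assert sorted(surr.tokens) == sorted(session.tokens)

    def test_both_orders_of_two_symbols_appear(self):
        seq = make_seq("AB")
        seen = {shuffle_surrogate(seq, s).tokens for s in range(30)}
        assert seen == {("A", "B"), ("B", "A")}


class TestNormalizedComplexity:
    def test_random_message_near_one(self, random_binary_seq):
        norm = normalized_complexity(random_binary_seq, lz_complexity,
                                     n_surr=99, seed=0)
        assert abs(norm.c_n - 1.0) < 3 * norm.sd_surrogate / norm.mean_surrogate

    def test_constant_message_near_zero(self, constant_seq):
        for measure in (lz_complexity, grammar_complexity):
            norm = normalized_complexity(constant_seq, measure, n_surr=49, seed=0)
            assert norm.c_n < 0.1

    def test_shuffle_normalization_refused(self, constant_seq):
        with pytest.raises(ValueError, match="shuffle"):
            normalized_complexity(constant_seq, lz_complexity,
                                  surrogate_kind="shuffle", n_surr=10, seed=0)

    def test_ratio_definition(self, random_binary_seq):
        norm = normalized_complexity(random_binary_seq, lz_complexity,
                                     n_surr=20, seed=4)
        assert norm.c_n == pytest.approx(norm.c_orig / norm.mean_surrogate)
        assert norm.delta_c_n >= norm.c_n * norm.sd_surrogate / norm.mean_surrogate


class TestMonteCarloPNull:
    def test_structured_message_reaches_minimum(self):
        seq = make_seq("01" * 500)
        p = monte_carlo_pnull(seq, lz_complexity, "equiprobable",
                              n_surr=499, seed=0)
        assert p == pytest.approx(0.002)

    def test_maximum_when_all_surrogates_below(self, constant_seq):
        # a constant message has minimal complexity, so invert the roles:
        # test a random message against markov surrogates of itself would tie;
        # instead check the arithmetic ceiling with a measure that favors
        # the original
        seq = make_seq("01" * 500)

        def inverted(s):
            res = lz_complexity(s)
            res.value = -res.value
            return res

        p = monte_carlo_pnull(seq, inverted, "equiprobable", n_surr=19, seed=0)
        assert p == 1.0

    def test_self_tie_included_in_numerator(self):
        # markov surrogates of ABAB are ABAB itself: every comparison ties
        seq = make_seq("ABAB")
        p = monte_carlo_pnull(seq, lz_complexity, "markov", n_surr=19, seed=0)
        assert p == 1.0


class TestBarnardHope:
    def test_rejection_probability(self):
        seq = make_seq("01" * 500)
        res = barnard_hope_reject(seq, lz_complexity, "equiprobable",
                                  n_surr=19, seed=0)
        assert res.rejected and res.probability == pytest.approx(0.05)

    def test_tie_blocks_rejection(self):
        seq = make_seq("ABAB")
        res = barnard_hope_reject(seq, lz_complexity, "markov", n_surr=9, seed=0)
        assert not res.rejected and res.probability is None


class TestRatesAndQuarters:
    def test_rate_arithmetic(self):
        from symdyn.grammar import ComplexityResult
        res = ComplexityResult("grammar", 27.585, 32)
        assert complexity_generation_rate(res, 60.0) == pytest.approx(0.4598, abs=5e-5)

    def test_zero_duration_rejected(self):
        from symdyn.grammar import ComplexityResult
        with pytest.raises(ValueError):
            complexity_generation_rate(ComplexityResult("grammar", 1.0, 1), 0.0)

    def test_quarter_sizes_317(self, session):
        quarters = quarter_profile(session, 60.0, lz_complexity, n_surr=9, seed=0)
        assert len(quarters) == 4
        # sizes 80, 79, 79, 79: recompute rates from the blocks directly
        sizes = [80, 79, 79, 79]
        pos = 0
        for q, size in zip(quarters, sizes):
            block = session[pos:pos + size]
            pos += size
            assert q.rate == pytest.approx(lz_complexity(block).value / 15.0)

    def test_quarter_cn_extremes(self):
        const = SymbolSequence(("1",) * 4000, Alphabet(("0", "1")))
        quarters = quarter_profile(const, 60.0, lz_complexity, n_surr=19, seed=0)
        assert all(q.normalized.c_n < 0.1 for q in quarters)
        rng = np.random.default_rng(3)
        rand = SymbolSequence(tuple(str(b) for b in rng.integers(0, 2, 4000)))
        quarters = quarter_profile(rand, 60.0, lz_complexity, n_surr=19, seed=0)
        for q in quarters:
            sd_rel = q.normalized.sd_surrogate / q.normalized.mean_surrogate
            assert abs(q.normalized.c_n - 1.0) < 3 * sd_rel
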