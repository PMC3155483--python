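"""Surrogate ensembles, normalized complexity and Monte Carlo null tests.

Two null hypotheses are supported.  The *equiprobable* null states that the
sequential structure of the message is indistinguishable from an iid uniform
sequence of the same length over the same alphabet; it is the basis of the
normalized complexity C_N = C_ORIG / <C_S>.  The *first-order Markov* null
preserves, in addition to length, the full pair-transition structure of the
original message: Markov surrogates are constrained randomizations with
exactly the same pair-count matrix (random Eulerian path on the transition
multigraph).  Shuffle surrogates (random permutations) are provided for
contrast only and are rejected for normalization: a constant message would
score C_N = 1 against its own shuffles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .grammar import ComplexityResult, UncertaintyEstimate, complexity_uncertainty
from .sequences import Alphabet, SymbolSequence

__all__ = [
    "TransitionMatrix", "SurrogateEnsemble", "NormalizedComplexity",
    "estimate_transition_matrix", "equiprobable_surrogate", "markov_surrogate",
    "shuffle_surrogate", "surrogate_ensemble", "normalized_complexity",
    "monte_carlo_pnull", "barnard_hope_reject", "complexity_generation_rate",
    "quarter_profile", "surrogate_test",
]

Measure = Callable[[SymbolSequence], ComplexityResult]


@dataclass
class TransitionMatrix:
    """First-order pair counts O(i, j) and row-normalized probabilities
    P(i, j) over an alphabet."""

    alphabet: Alphabet
    counts: np.ndarray
    probabilities: np.ndarray

    def probability(self, a: str, b: str) -> float:
        idx = self.alphabet.index()
        return float(self.probabilities[idx[a], idx[b]])


def estimate_transition_matrix(seq: SymbolSequence) -> TransitionMatrix:
    """Pair counts from all L-1 adjacent pairs; rows with zero count keep
    zero probabilities."""
    if len(seq) < 2:
        raise ValueError("transition estimation requires a sequence of length >= 2")
    n = seq.alphabet.size
    idx = seq.alphabet.index()
    codes = [idx[t] for t in seq.tokens]
    counts = np.zeros((n, n), dtype=np.int64)
    for a, b in zip(codes[:-1], codes[1:]):
        counts[a, b] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / np.where(row == 0, 1, row), 0.0)
    return TransitionMatrix(seq.alphabet, counts, probs)


def equiprobable_surrogate(length: int, alphabet: Alphabet,
                           seed: int) -> SymbolSequence:
    """iid uniform draws over the alphabet."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, alphabet.size, size=length)
    return SymbolSequence(tuple(alphabet.symbols[d] for d in draws), alphabet,
                          {"surrogate": "equiprobable", "seed": int(seed)})


def markov_surrogate(seq: SymbolSequence, seed: int) -> SymbolSequence:
    """Constrained randomization preserving length, first symbol and the full
    pair-count matrix.

    The adjacent pairs of the message are the edges of a multigraph on the
    alphabet; the message itself is an Eulerian path through that multigraph
    starting at its first symbol, so a valid surrogate always exists.  A
    random Eulerian path is drawn by Hierholzer's algorithm with the out-edge
    list of every node shuffled by the seeded generator.
    """
    if len(seq) < 2:
        raise ValueError("a Markov surrogate requires a sequence of length >= 2")
    rng = np.random.default_rng(seed)
    idx = seq.alphabet.index()
    codes = [idx[t] for t in seq.tokens]
    out: dict = {}
    for a, b in zip(codes[:-1], codes[1:]):
        out.setdefault(a, []).append(b)
    for a in out:
        rng.shuffle(out[a])
    ptr = {a: 0 for a in out}
    stack = [codes[0]]
    path = []
    while stack:
        v = stack[-1]
        edges = out.get(v)
        if edges is not None and ptr[v] < len(edges):
            w = edges[ptr[v]]
            ptr[v] += 1
            stack.append(w)
        else:
            path.append(stack.pop())
    path.reverse()
    tokens = tuple(seq.alphabet.symbols[c] for c in path)
    return SymbolSequence(tokens, seq.alphabet,
                          {"surrogate": "markov", "seed": int(seed)})


def shuffle_surrogate(seq: SymbolSequence, seed: int) -> SymbolSequence:
    """Uniform random permutation of the tokens (symbol counts preserved)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seq))
    tokens = tuple(seq.tokens[i] for i in perm)
    return SymbolSequence(tokens, seq.alphabet,
                          {"surrogate": "shuffle", "seed": int(seed)})


@dataclass
class SurrogateEnsemble:
    """Per-surrogate complexity values under one surrogate kind."""

    kind: str
    n_surr: int
    seed: int
    measure: str
    complexities: np.ndarray = field(default_factory=lambda: np.array([]))


def _surrogate_alphabet(seq: SymbolSequence, full_alphabet: bool) -> Alphabet:
    # default: restrict to symbols actually observed (codes that never occur
    # carry no sequential information); full declared alphabet by flag.
    # A degenerate observed alphabet (constant message) falls back to the
    # declared one — normalization against single-symbol surrogates would be
    # meaningless.
    if full_alphabet:
        return seq.alphabet
    observed = seq.observed_alphabet()
    return observed if observed.size >= 2 else seq.alphabet


def surrogate_ensemble(seq: SymbolSequence, measure: Measure, kind: str,
                       n_surr: int, seed: int,
                       full_alphabet: bool = False) -> SurrogateEnsemble:
    """Generate ``n_surr`` surrogates of the requested kind and measure the
    complexity of each; child seeds derive deterministically from ``seed``."""
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n_surr)
    values = np.empty(n_surr)
    if kind == "equiprobable":
        alpha = _surrogate_alphabet(seq, full_alphabet)
        for i, s in enumerate(child_seeds):
            values[i] = measure(equiprobable_surrogate(len(seq), alpha, int(s))).value
    elif kind == "markov":
        for i, s in enumerate(child_seeds):
            values[i] = measure(markov_surrogate(seq, int(s))).value
    elif kind == "shuffle":
        for i, s in enumerate(child_seeds):
            values[i] = measure(shuffle_surrogate(seq, int(s))).value
    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")
    return SurrogateEnsemble(kind=kind, n_surr=n_surr, seed=int(seed),
                             measure=getattr(measure, "__name__", "measure"),
                             complexities=values)


@dataclass
class NormalizedComplexity:
    """C_N = C_ORIG / <C_S> against equiprobable surrogates, with propagated
    uncertainty."""

    c_n: float
    delta_c_n: float
    c_orig: float
    delta_c_orig: float
    mean_surrogate: float
    sd_surrogate: float
    n_surr: int
    seed: int
    measure: str


def normalized_complexity(seq: SymbolSequence, measure: Measure,
                          n_surr: int = 499, seed: int = 0,
                          surrogate_kind: str = "equiprobable",
                          uncertainty_method: str = "half_split",
                          full_alphabet: bool = False) -> NormalizedComplexity:
    """Normalized complexity of a message.

    Values are close to zero for a constant message and close to one for a
    random one, and are independent of message length — the normalization
    separates intrinsic sequential structure from message size.  The
    uncertainty combines the single-message uncertainty of C_ORIG and the
    surrogate-distribution standard deviation in quadrature.
    """
    if surrogate_kind == "shuffle":
        raise ValueError(
            "normalized complexity cannot be formed against shuffle surrogates: "
            "a constant message would score C_N = 1; use equiprobable surrogates")
    if surrogate_kind != "equiprobable":
        raise ValueError(
            "normalized complexity is defined against equiprobable surrogates")
    if n_surr < 2:
        raise ValueError("n_surr must be >= 2")
    c_orig = measure(seq).value
    if len(seq) >= 4:
        delta_orig = complexity_uncertainty(seq, measure,
                                            method=uncertainty_method,
                                            seed=seed).value
    else:
        delta_orig = 0.0
    ens = surrogate_ensemble(seq, measure, "equiprobable", n_surr, seed,
                             full_alphabet=full_alphabet)
    mean_s = float(ens.complexities.mean())
    sd_s = float(ens.complexities.std(ddof=1))
    c_n = c_orig / mean_s
    delta_c_n = c_n * math.sqrt((delta_orig / c_orig) ** 2 + (sd_s / mean_s) ** 2)
    return NormalizedComplexity(c_n=c_n, delta_c_n=delta_c_n, c_orig=c_orig,
                                delta_c_orig=delta_orig, mean_surrogate=mean_s,
                                sd_surrogate=sd_s, n_surr=n_surr, seed=int(seed),
                                measure=getattr(measure, "__name__", "measure"))


def monte_carlo_pnull(seq: SymbolSequence, measure: Measure,
                      surrogate_kind: str = "equiprobable",
                      n_surr: int = 499, seed: int = 0,
                      full_alphabet: bool = False) -> float:
    """Monte Carlo probability of the surrogate null hypothesis.

    P_NULL = (1 + #{surrogates with C <= C_ORIG}) / (1 + N_SURR): one-sided
    with low complexity indicating structure; the original message is included
    in the numerator so the minimum attainable value is 1/(1 + N_SURR).  Ties
    count against rejection.
    """
    c_orig = measure(seq).value
    ens = surrogate_ensemble(seq, measure, surrogate_kind, n_surr, seed,
                             full_alphabet=full_alphabet)
    below = int(np.sum(ens.complexities <= c_orig))
    return (1 + below) / (1 + n_surr)


@dataclass
class BarnardHopeResult:
    rejected: bool
    probability: Optional[float]
    n_surr: int


def barnard_hope_reject(seq: SymbolSequence, measure: Measure,
                        surrogate_kind: str = "equiprobable",
                        n_surr: int = 499, seed: int = 0,
                        full_alphabet: bool = False) -> BarnardHopeResult:
    """Barnard/Hope criterion: reject iff C_ORIG is strictly below every
    surrogate complexity; on rejection the probability is 1/(1 + N_SURR)."""
    c_orig = measure(seq).value
    ens = surrogate_ensemble(seq, measure, surrogate_kind, n_surr, seed,
                             full_alphabet=full_alphabet)
    rejected = bool(np.all(ens.complexities > c_orig))
    prob = 1.0 / (1 + n_surr) if rejected else None
    return BarnardHopeResult(rejected=rejected, probability=prob, n_surr=n_surr)


def complexity_generation_rate(result: ComplexityResult,
                               duration_minutes: float) -> float:
    """Complexity per unit observation time, in bits/minute."""
    if duration_minutes is None or duration_minutes <= 0:
        raise ValueError("duration must be a positive number of minutes")
    return result.value / duration_minutes


@dataclass
class QuarterResult:
    rate: float
    normalized: NormalizedComplexity


def quarter_profile(seq: SymbolSequence, duration_minutes: float,
                    measure: Measure, n_surr: int = 499,
                    seed: int = 0) -> list:
    """Within-session profile: the message is split into four consecutive
    blocks of near-equal size (remainder to the earliest quarters); each block
    is analyzed independently with per-quarter duration = duration/4."""
    L = len(seq)
    if L < 4:
        raise ValueError("quarter profile requires a message of length >= 4")
    if duration_minutes is None or duration_minutes <= 0:
        raise ValueError("duration must be a positive number of minutes")
    base, rem = divmod(L, 4)
    sizes = [base + 1 if q < rem else base for q in range(4)]
    rng = np.random.default_rng(seed)
    quarter_seeds = rng.integers(0, 2 ** 31 - 1, size=4)
    results = []
    pos = 0
    for size, qseed in zip(sizes, quarter_seeds):
        block = seq[pos:pos + size]
        pos += size
        rate = measure(block).value / (duration_minutes / 4.0)
        norm = normalized_complexity(block, measure, n_surr=n_surr,
                                     seed=int(qseed))
        results.append(QuarterResult(rate=rate, normalized=norm))
    return results


def surrogate_test(seq: SymbolSequence, measure: Measure,
                   surrogate_kind: str = "equiprobable",
                   n_surr: int = 499, seed: int = 0,
                   full_alphabet: bool = False) -> dict:
    """One-stop surrogate report: C_ORIG, ensemble statistics, Monte Carlo
    P_NULL and the Barnard/Hope criterion, sharing a single ensemble."""
    c_orig = measure(seq).value
    ens = surrogate_ensemble(seq, measure, surrogate_kind, n_surr, seed,
                             full_alphabet=full_alphabet)
    below = int(np.sum(ens.complexities <= c_orig))
    p_null = (1 + below) / (1 + n_surr)
    rejected = bool(np.all(ens.complexities > c_orig))
    return {
        "measure": getattr(measure, "__name__", "measure"),
        "surrogate_kind": surrogate_kind,
        "n_surr": n_surr,
        "seed": int(seed),
        "c_orig": c_orig,
        "mean_surrogate": float(ens.complexities.mean()),
        "sd_surrogate": float(ens.complexities.std(ddof=1)) if n_surr > 1 else 0.0,
        "p_null": p_null,
        "barnard_hope_rejected": rejected,
    }
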