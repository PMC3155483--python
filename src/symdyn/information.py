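"""Mutual information, chi-square independence tests, block and conditional
entropies for symbol sequences.

All logarithms are base 2; units are bits.  Estimators are plug-in
(maximum-likelihood) with the convention 0*log(0) = 0; a pluggable estimator
slot on the entropy profile allows bias-corrected alternatives without
changing the interface.  Plug-in block entropies H_n approach log2(L) as n
grows — for short messages the n-word statistics degrade quickly, which the
good-statistics flag (expected count per possible n-word of order ten) makes
explicit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .sequences import Alphabet, SymbolSequence

__all__ = [
    "JointDistribution", "MIProfile", "EntropyProfile", "MIComparison",
    "joint_distribution", "mutual_information", "shifted_self_information",
    "pair_independence_test", "block_entropy", "conditional_entropy",
    "entropy_profile", "good_statistics_check", "entropy_limit",
    "compare_mi_profiles",
]


@dataclass
class JointDistribution:
    """Empirical joint distribution of two aligned symbol sequences."""

    alphabet_a: Alphabet
    alphabet_b: Alphabet
    joint_counts: np.ndarray
    n_pairs: int

    @property
    def joint_probabilities(self) -> np.ndarray:
        return self.joint_counts / self.n_pairs

    @property
    def marginal_a(self) -> np.ndarray:
        return self.joint_probabilities.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.joint_probabilities.sum(axis=0)


def _codes(seq: SymbolSequence) -> np.ndarray:
    idx = seq.alphabet.index()
    return np.fromiter((idx[t] for t in seq.tokens), dtype=np.intp,
                       count=len(seq))


def joint_distribution(seq_a: SymbolSequence,
                       seq_b: SymbolSequence) -> JointDistribution:
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences must have equal length ({len(seq_a)} != {len(seq_b)})")
    na, nb = seq_a.alphabet.size, seq_b.alphabet.size
    flat = _codes(seq_a) * nb + _codes(seq_b)
    counts = np.bincount(flat, minlength=na * nb).reshape(na, nb)
    return JointDistribution(seq_a.alphabet, seq_b.alphabet, counts, len(seq_a))


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    mask = p > 0
    outer = np.outer(pa, pb)
    return float(np.sum(p[mask] * np.log2(p[mask] / outer[mask])))


def mutual_information(seq_a: SymbolSequence, seq_b: SymbolSequence) -> float:
    """Average mutual information I(A, B) in bits, from the empirical plug-in
    joint distribution of the two aligned sequences.  I(A, A) is the order-1
    entropy (self-information); independent processes give 0."""
    return _mi_from_counts(joint_distribution(seq_a, seq_b).joint_counts)


def _chi2_from_counts(counts: np.ndarray, n_alpha: int):
    n = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row * col / n
    mask = expected > 0
    chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    dof = (n_alpha - 1) ** 2
    p = float(stats.chi2.sf(chi2, dof))  # Q(nu/2, chi2/2)
    return chi2, dof, p


def _shift_counts(seq: SymbolSequence, k: int) -> np.ndarray:
    codes = _codes(seq)
    n = seq.alphabet.size
    a = codes[:len(codes) - k] if k else codes
    b = codes[k:]
    flat = a * n + b
    return np.bincount(flat, minlength=n * n).reshape(n, n)


@dataclass
class MIProfile:
    """Time-shifted self-information I(A_i, A_{i+K}) with per-shift
    chi-square independence tests.

    K = 0 pairs the sequence with itself, so I equals the order-1 entropy and
    the independence null is rejected by construction for any non-constant
    message.  The decay of I with K measures temporal decorrelation.
    """

    shifts: np.ndarray
    values: np.ndarray
    chi2: np.ndarray
    dof: int
    p_values: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"K": self.shifts, "I_bits": self.values,
                             "chi2": self.chi2, "dof": self.dof,
                             "p": self.p_values})


def shifted_self_information(seq: SymbolSequence, k_max: int) -> MIProfile:
    """Mutual information between the message and its K-shifted copy, using
    the pairs (A_i, A_{i+K}) for i = 1 ... L-K, for K = 0 ... k_max."""
    if k_max >= len(seq):
        raise ValueError(f"k_max={k_max} must be smaller than the length {len(seq)}")
    n_alpha = seq.alphabet.size
    shifts = np.arange(k_max + 1)
    values = np.empty(k_max + 1)
    chi2s = np.empty(k_max + 1)
    ps = np.empty(k_max + 1)
    dof = (n_alpha - 1) ** 2
    for k in shifts:
        counts = _shift_counts(seq, int(k))
        values[k] = _mi_from_counts(counts)
        chi2s[k], _, ps[k] = _chi2_from_counts(counts, n_alpha)
    return MIProfile(shifts=shifts, values=values, chi2=chi2s, dof=dof,
                     p_values=ps)


def pair_independence_test(seq: SymbolSequence, k: int):
    """Chi-square test of independence of the K-shifted pairing.

    Expected counts come from the contingency table's own margins; cells with
    zero expectation are excluded.  Degrees of freedom are nu = (N_alpha - 1)^2
    with N_alpha the declared alphabet size; the p-value is the upper
    incomplete-gamma tail Q(nu/2, chi2/2).

    Returns ``(chi2, dof, p)``.
    """
    if not 0 <= k < len(seq):
        raise ValueError(f"shift k={k} must satisfy 0 <= k < {len(seq)}")
    return _chi2_from_counts(_shift_counts(seq, k), seq.alphabet.size)


# ---------------------------------------------------------------------------
# Block and conditional entropies
# ---------------------------------------------------------------------------

def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def block_entropy(seq: SymbolSequence, n: int,
                  estimator: Optional[Callable[[np.ndarray], float]] = None) -> float:
    """Shannon entropy H_n (bits) of the L - n + 1 overlapping n-words.

    ``estimator`` maps an n-word count vector to an entropy estimate; default
    is the maximum-likelihood plug-in.
    """
    L = len(seq)
    if not 1 <= n <= L:
        raise ValueError(f"order n={n} must satisfy 1 <= n <= {L}")
    counts = np.fromiter(Counter(seq.tokens[i:i + n]
                                 for i in range(L - n + 1)).values(),
                         dtype=np.int64)
    return (estimator or _plugin_entropy)(counts)


def good_statistics_check(length: int, alphabet_size: int, n: int):
    """Expected appearances of each possible n-word under equiprobability,
    <N_i> = (L - n + 1)/N_alpha^n, and whether it reaches the order-ten
    threshold for a trustworthy plug-in estimate.

    Returns ``(expected_count, flag)``.
    """
    expected = (length - n + 1) / alphabet_size ** n
    return expected, expected >= 10.0


def entropy_limit(length: int) -> float:
    """Large-n limit of H_n for a maximally disordered message: log2(L)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return math.log2(length)


@dataclass
class EntropyProfile:
    """Block entropies H_n and conditional entropies h_n = H_{n+1} - H_n.

    ``h`` is indexed by context order: ``h[0] = H_1`` (no context),
    ``h[n] = H_{n+1} - H_n``.  ``good_statistics`` flags the orders whose
    n-word statistics support the plug-in estimate; ``limit`` is log2(L), the
    ceiling the estimates approach as n grows.
    """

    orders: np.ndarray
    H: np.ndarray
    h: np.ndarray
    expected_counts: np.ndarray
    good_statistics: np.ndarray
    limit: float
    length: int
    alphabet_size: int
    estimator: str = "plugin"

    def to_frame(self):
        import pandas as pd
        h_at_order = [self.h[n] if n < len(self.h) else np.nan
                      for n in self.orders]
        return pd.DataFrame({"n": self.orders, "H_n": self.H,
                             "h_n": h_at_order,
                             "expected_count": self.expected_counts,
                             "good_statistics": self.good_statistics})


def entropy_profile(seq: SymbolSequence, n_max: int = 5,
                    estimator: Optional[Callable[[np.ndarray], float]] = None
                    ) -> EntropyProfile:
    """H_n for n = 1 ... n_max (plus H_{n_max+1} when available, to supply
    h_{n_max}) with good-statistics flags."""
    L = len(seq)
    if not 1 <= n_max <= L:
        raise ValueError(f"n_max={n_max} must satisfy 1 <= n_max <= {L}")
    top = min(n_max + 1, L)
    H_all = np.array([block_entropy(seq, n, estimator)
                      for n in range(1, top + 1)])
    h = np.empty(top)
    h[0] = H_all[0]
    h[1:] = np.diff(H_all)
    orders = np.arange(1, n_max + 1)
    stats_pairs = [good_statistics_check(L, seq.alphabet.size, n) for n in orders]
    return EntropyProfile(
        orders=orders,
        H=H_all[:n_max],
        h=h[:n_max + 1],
        expected_counts=np.array([e for e, _ in stats_pairs]),
        good_statistics=np.array([f for _, f in stats_pairs]),
        limit=entropy_limit(L),
        length=L,
        alphabet_size=seq.alphabet.size,
        estimator="plugin" if estimator is None else
        getattr(estimator, "__name__", "custom"),
    )


def conditional_entropy(profile: EntropyProfile, n: int) -> float:
    """h_n = H_{n+1} - H_n: information needed to predict the next symbol
    given an n-symbol context; h_0 = H_1."""
    if not 0 <= n < len(profile.h):
        raise ValueError(f"h_{n} is not available in this profile "
                         f"(orders 0 ... {len(profile.h) - 1})")
    return float(profile.h[n])


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------

@dataclass
class MIComparison:
    """Paired t-test on per-shift mutual-information differences."""

    t: Optional[float]
    p: Optional[float]
    dof: int
    mean_difference: float
    n_shifts: int
    degenerate: bool = False


def compare_mi_profiles(profile_a: MIProfile, profile_b: MIProfile,
                        k_range: Optional[range] = None) -> MIComparison:
    """Two-sided paired t-test across shifts of two MI profiles.

    Zero-variance differences (e.g. a profile against itself) are flagged
    degenerate rather than raising.
    """
    if k_range is None:
        k_range = range(int(min(profile_a.shifts.max(),
                                profile_b.shifts.max())) + 1)
    ks = list(k_range)
    if len(ks) < 2:
        raise ValueError("at least two shifts are required")
    for prof in (profile_a, profile_b):
        if min(ks) < prof.shifts.min() or max(ks) > prof.shifts.max():
            raise ValueError("both profiles must cover the requested shift range")
    a = profile_a.values[np.isin(profile_a.shifts, ks)]
    b = profile_b.values[np.isin(profile_b.shifts, ks)]
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return MIComparison(t=None, p=None, dof=len(ks) - 1,
                            mean_difference=float(diffs.mean()),
                            n_shifts=len(ks), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return MIComparison(t=float(t), p=float(p), dof=len(ks) - 1,
                        mean_difference=float(diffs.mean()),
                        n_shifts=len(ks))
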