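"""Symbol frequency tables and repeated n-tuple (n-word) analysis.

All windows are overlapping: a message of length L contains L - n + 1
n-words, which is also the frequency denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .sequences import SymbolSequence

__all__ = ["NGramTable", "symbol_frequencies", "repeated_ngrams",
           "expected_ngram_frequency"]


@dataclass
class NGramTable:
    """Counts and frequencies of n-grams (token tuples) of a fixed order.

    ``denominator`` is the number of overlapping n-gram positions,
    L - n + 1; frequencies are count / denominator.
    """

    order: int
    entries: dict = field(default_factory=dict)  # tuple -> (count, frequency)
    denominator: int = 0

    def count(self, ngram) -> int:
        return self.entries.get(tuple(ngram), (0, 0.0))[0]

    def frequency(self, ngram) -> float:
        return self.entries.get(tuple(ngram), (0, 0.0))[1]

    def total_count(self) -> int:
        return sum(c for c, _ in self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        """Table as a DataFrame with columns ngram, count, frequency;
        n-grams rendered as tokens joined by '|'."""
        rows = [("|".join(ng), c, f) for ng, (c, f) in self.entries.items()]
        return pd.DataFrame(rows, columns=["ngram", "count", "frequency"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sorted_entries(counts: Counter, denom: int, threshold: float) -> dict:
    entries = {}
    for ng, c in counts.items():
        f = c / denom
        if f >= threshold:
            entries[ng] = (c, f)
    # descending frequency, then lexicographic on the token tuple
    ordered = sorted(entries.items(), key=lambda kv: (-kv[1][1], kv[0]))
    return dict(ordered)


def symbol_frequencies(seq: SymbolSequence) -> NGramTable:
    """Order-1 frequency table over the declared alphabet; symbols absent
    from the sequence are reported with frequency 0."""
    L = len(seq)
    counts = Counter((t,) for t in seq.tokens)
    entries = _sorted_entries(counts, L, 0.0)
    for s in seq.alphabet.symbols:
        entries.setdefault((s,), (0, 0.0))
    return NGramTable(order=1, entries=entries, denominator=L)


def repeated_ngrams(seq: SymbolSequence, n: int,
                    min_frequency: float = 0.0) -> NGramTable:
    """Overlapping n-gram table filtered to entries with frequency >=
    ``min_frequency``, sorted by descending frequency (ties lexicographic)."""
    L = len(seq)
    if not 1 <= n <= L:
        raise ValueError(f"order n={n} must satisfy 1 <= n <= {L}")
    denom = L - n + 1
    toks = seq.tokens
    counts = Counter(toks[i:i + n] for i in range(denom))
    return NGramTable(order=n, entries=_sorted_entries(counts, denom, min_frequency),
                      denominator=denom)


def expected_ngram_frequency(alphabet_size: int, n: int) -> float:
    """Expected frequency of a specific n-gram under an iid equiprobable
    alphabet: 1 / N_alpha**n."""
    if alphabet_size < 1 or n < 1:
        raise ValueError("alphabet_size and n must be >= 1")
    return 1.0 / alphabet_size ** n
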