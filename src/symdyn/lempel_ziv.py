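"""Lempel-Ziv (1976) phrase decomposition and complexity.

The message is parsed left to right into phrases.  The first phrase is the
first symbol alone.  Each subsequent phrase grows symbol by symbol while the
candidate phrase is still an element of the vocabulary (set of contiguous
substrings) of everything consumed so far including the candidate, minus its
last symbol; the first violating symbol closes the phrase.  The final phrase
may end while still in the vocabulary.  The complexity C_LZ is the number of
phrases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .grammar import ComplexityResult
from .sequences import SymbolSequence

__all__ = ["LZDecomposition", "vocabulary", "lz_decompose", "lz_complexity"]


def _encode(seq: SymbolSequence) -> str:
    """Map tokens to single unicode characters so substring search runs at
    C speed regardless of token length."""
    table = {s: chr(0x100 + i) for i, s in enumerate(seq.alphabet.symbols)}
    return "".join(table[t] for t in seq.tokens)


def vocabulary(seq: SymbolSequence) -> set:
    """All distinct non-empty contiguous substrings (as token tuples),
    including the message itself."""
    toks = seq.tokens
    L = len(toks)
    return {toks[i:j] for i in range(L) for j in range(i + 1, L + 1)}


@dataclass
class LZDecomposition:
    """Ordered phrase list of the Lempel-Ziv parsing.

    ``phrases`` are token tuples whose concatenation is the original message;
    ``complexity`` is the phrase count.
    """

    phrases: list
    message_length: int

    @property
    def complexity(self) -> int:
        return len(self.phrases)

    def starts(self) -> list:
        """1-based start position of each phrase."""
        out, pos = [], 1
        for p in self.phrases:
            out.append(pos)
            pos += len(p)
        return out

    def to_json(self) -> str:
        """JSON export with, for each phrase, the three-quantity encoding:
        1-based index where the phrase minus its last symbol appears earlier
        in the message, the phrase length, and its final symbol."""
        toks: tuple = ()
        for p in self.phrases:
            toks = toks + tuple(p)
        records = []
        consumed = 0
        for start, phrase in zip(self.starts(), self.phrases):
            head = tuple(phrase[:-1])
            if head:
                prior = _find(toks[:consumed + len(phrase) - 1], head)
                prior_index = prior + 1  # 1-based
            else:
                prior_index = None
            records.append({"start": start, "phrase": list(phrase),
                            "prior_index": prior_index,
                            "length": len(phrase), "last_symbol": phrase[-1]})
            consumed += len(phrase)
        return json.dumps({"complexity": len(self.phrases),
                           "phrases": records}, indent=2)


def _find(haystack: tuple, needle: tuple) -> int:
    n = len(needle)
    for i in range(len(haystack) - n + 1):
        if haystack[i:i + n] == needle:
            return i
    return -1


def lz_decompose(seq: SymbolSequence) -> LZDecomposition:
    """Deterministic Lempel-Ziv parsing of a message."""
    s = _encode(seq)
    toks = seq.tokens
    L = len(s)
    phrases = []
    i = 0
    while i < L:
        j = i + 1
        # candidate s[i:j]; vocabulary of consumed-plus-candidate minus last
        # symbol is the set of substrings of s[:j-1]
        while j < L and s[i:j] in s[:j - 1]:
            j += 1
        phrases.append(toks[i:j])
        i = j
    return LZDecomposition(phrases=phrases, message_length=L)


def lz_complexity(seq: SymbolSequence) -> ComplexityResult:
    """Lempel-Ziv complexity: the integer phrase count of the parsing."""
    decomposition = lz_decompose(seq)
    return ComplexityResult(measure="lempel_ziv",
                            value=float(decomposition.complexity),
                            message_length=len(seq))
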