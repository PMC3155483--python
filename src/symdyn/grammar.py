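"""Context-free grammar complexity by hierarchical pattern substitution.

A message is compressed into an instruction set: a main body plus an ordered
list of productions (new nonterminal symbols standing for repeated patterns),
with maximal runs of identical items rewritten in exponent notation.  The
complexity of the message is the size of that instruction set: each symbol in
the main body or a production body counts one, and an exponent k contributes
log2(k).  Production left-hand sides and separators are free.  The value is an
upper bound on the true algorithmic complexity — an alternative construction
could always yield a smaller instruction set — but the procedure is
deterministic, so values are comparable across messages.

Compression schedule
--------------------
1. *Pairs*: repeatedly replace the most frequent adjacent pair (non-overlapping
   occurrences, greedy left-to-right, counted across the main body and every
   production body) while the count is at least 3.  Replacing a pair that
   appears only twice does not shrink the instruction set.
2. *n-tuples* (n = 3, 4, ...): repeatedly replace the most frequent n-tuple
   occurring at least twice; for n >= 3 a replacement pays even at two
   occurrences.  Two non-overlapping occurrences of an (n+1)-tuple contain two
   non-overlapping occurrences of its n-prefix, so the first order with no
   repeats ends the search.
3. *Exponents*: every maximal run of k >= 2 identical items becomes item^k.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .sequences import SymbolSequence

__all__ = ["GrammarDerivation", "ComplexityResult", "UncertaintyEstimate",
           "grammar_compress", "grammar_complexity", "complexity_uncertainty"]

_GREEK = ("α", "β", "γ", "δ", "ε", "ζ",
          "η", "θ", "ι", "κ", "λ", "μ")


def _nonterminal_name(idx: int) -> str:
    return _GREEK[idx] if idx < len(_GREEK) else f"N{idx}"


@dataclass
class ComplexityResult:
    """A complexity measurement of a message.

    ``value`` is the real-valued total (used for downstream arithmetic such as
    normalization and rates); ``bits`` is the integer part reported for
    display.  For the Lempel-Ziv measure the value is already an integer
    phrase count.
    """

    measure: str
    value: float
    message_length: int
    uncertainty: Optional[float] = None

    @property
    def bits(self) -> int:
        return int(math.floor(self.value))


@dataclass
class GrammarDerivation:
    """Instruction set produced by the grammar compressor.

    Items are terminals (tokens of the original alphabet) or nonterminal ids
    (integers indexing ``productions``).  After exponent rewriting each body
    is a list of ``(item, k)`` entries with k >= 1; an entry with k >= 2
    renders as ``item^k``.  Production i may reference only productions
    created earlier.
    """

    main_body: list
    productions: list
    trace: list = field(default_factory=list)

    def expand(self) -> tuple:
        """Losslessly reconstruct the original message tokens."""
        expanded: list = []
        for body in self.productions:
            expanded.append(self._expand_body(body, expanded))
        return self._expand_body(self.main_body, expanded)

    @staticmethod
    def _expand_body(body, expanded) -> tuple:
        out: list = []
        for item, k in body:
            unit = expanded[item] if isinstance(item, int) else (item,)
            out.extend(unit * k)
        return tuple(out)

    def complexity_value(self) -> float:
        """Instruction-set size: one per item plus log2 of each exponent;
        left-hand sides contribute nothing."""
        total = 0.0
        for body in [self.main_body] + list(self.productions):
            for _, k in body:
                total += 1.0
                if k >= 2:
                    total += math.log2(k)
        return total

    # -- rendering ----------------------------------------------------------

    @staticmethod
    def _render_item(item, k) -> str:
        name = _nonterminal_name(item) if isinstance(item, int) else str(item)
        return f"{name}^{k}" if k >= 2 else name

    def render(self) -> str:
        """Human-readable instruction set, e.g. ``γ = B^2 D``."""
        lines = ["M = " + " ".join(self._render_item(i, k) for i, k in self.main_body)]
        for idx, body in enumerate(self.productions):
            rhs = " ".join(self._render_item(i, k) for i, k in body)
            lines.append(f"{_nonterminal_name(idx)} = {rhs}")
        return "\n".join(lines)

    def to_json(self) -> str:
        def body_json(body):
            return [{"item": (_nonterminal_name(i) if isinstance(i, int) else i),
                     "nonterminal": isinstance(i, int), "exponent": k}
                    for i, k in body]

        return json.dumps({
            "main_body": body_json(self.main_body),
            "productions": [{"name": _nonterminal_name(i), "body": body_json(b)}
                            for i, b in enumerate(self.productions)],
            "trace": self.trace,
        }, indent=2)


# ---------------------------------------------------------------------------
# Compressor internals.  Working bodies are flat lists of items; exponents are
# introduced only in the final phase.
# ---------------------------------------------------------------------------

def _count_tuples(bodies, n):
    """Greedy left-to-right non-overlapping counts of every n-tuple, summed
    across bodies (occurrences never span a body boundary).  Also returns the
    global position of each tuple's first occurrence for tie-breaking."""
    counts: dict = {}
    first: dict = {}
    gpos = 0
    for body in bodies:
        last: dict = {}
        m = len(body) - n + 1
        for i in range(m):
            tup = tuple(body[i:i + n])
            if i >= last.get(tup, 0) or tup not in last:
                c = counts.get(tup, 0) + 1
                counts[tup] = c
                last[tup] = i + n
                if c == 1:
                    first[tup] = gpos + i
        gpos += len(body) + 1
    return counts, first


def _select(counts, first, min_count):
    """Most frequent tuple with count >= min_count; ties broken by leftmost
    first occurrence (unique)."""
    best = None
    best_key = None
    for tup, c in counts.items():
        if c < min_count:
            continue
        key = (-c, first[tup])
        if best_key is None or key < best_key:
            best, best_key = tup, key
    return best, (counts[best] if best is not None else 0)


def _replace(body, tup, nt):
    """Replace greedy left-to-right non-overlapping occurrences of ``tup``
    with nonterminal id ``nt``."""
    n = len(tup)
    out = []
    i = 0
    limit = len(body) - n
    while i <= limit:
        if tuple(body[i:i + n]) == tup:
            out.append(nt)
            i += n
        else:
            out.append(body[i])
            i += 1
    out.extend(body[i:])
    return out


def _run_length(body):
    out = []
    i = 0
    while i < len(body):
        j = i + 1
        while j < len(body) and body[j] == body[i]:
            j += 1
        out.append((body[i], j - i))
        i = j
    return out


def _render_pattern(tup) -> str:
    return " ".join(_nonterminal_name(i) if isinstance(i, int) else str(i)
                    for i in tup)


def grammar_compress(seq: SymbolSequence) -> GrammarDerivation:
    """Compress a message into its grammar instruction set (see module
    docstring for the three-phase schedule)."""
    bodies = [list(seq.tokens)]  # bodies[0] = main; bodies[1+i] = production i
    trace: list = []

    # Phase 1: pairs, while the best count is at least 3
    while True:
        counts, first = _count_tuples(bodies, 2)
        best, c = _select(counts, first, 3)
        if best is None:
            break
        nt = len(bodies) - 1
        bodies = [_replace(b, best, nt) for b in bodies]
        bodies.append(list(best))
        trace.append({"phase": "pairs", "pattern": _render_pattern(best),
                      "nonterminal": _nonterminal_name(nt), "count": c})

    # Phase 2: n-tuples for n = 3, 4, ... replaced while repeated (>= 2).
    # The first order with no repeated tuple exhausts the search: a repeated
    # (n+1)-tuple would imply a repeated n-tuple via its prefix.
    n = 3
    while n <= max(len(b) for b in bodies):
        counts, first = _count_tuples(bodies, n)
        best, c = _select(counts, first, 2)
        if best is None:
            break
        nt = len(bodies) - 1
        bodies = [_replace(b, best, nt) for b in bodies]
        bodies.append(list(best))
        trace.append({"phase": f"{n}-tuples", "pattern": _render_pattern(best),
                      "nonterminal": _nonterminal_name(nt), "count": c})

    # Phase 3: exponent rewriting of maximal runs
    rle = [_run_length(b) for b in bodies]
    return GrammarDerivation(main_body=rle[0], productions=rle[1:], trace=trace)


def grammar_complexity(seq: SymbolSequence) -> ComplexityResult:
    """Grammar complexity of a message, in bits.

    The real-valued total (e.g. 27.585) is kept in ``value``; the integer part
    is available as ``bits``.
    """
    derivation = grammar_compress(seq)
    return ComplexityResult(measure="grammar",
                            value=derivation.complexity_value(),
                            message_length=len(seq))


@dataclass
class UncertaintyEstimate:
    """Uncertainty of a complexity value estimated from sub-messages.

    ``value`` is the absolute uncertainty on the original complexity;
    ``fractional`` the relative form it was derived from.
    """

    value: float
    fractional: float
    method: str
    n_windows: int
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __float__(self):
        return float(self.value)


def complexity_uncertainty(seq: SymbolSequence,
                           measure: Callable[[SymbolSequence], ComplexityResult],
                           method: str = "substring_sample",
                           n_samples: int = 100,
                           seed: int = 0) -> UncertaintyEstimate:
    """Estimate the uncertainty of a single-message complexity value.

    ``half_split`` compares the complexities of the two halves of the message
    (fraction-of-average; zero when the halves agree, a documented aberrant
    case for homogeneous messages).  ``substring_sample`` uses the mean and
    standard deviation of the complexity of contiguous windows of length
    L//2 — all windows when L < 200, otherwise ``n_samples`` seeded random
    start positions.
    """
    L = len(seq)
    if L < 4:
        raise ValueError("uncertainty estimation requires a message of length >= 4")
    c_orig = measure(seq).value

    if method == "half_split":
        half = L // 2
        c_a = measure(seq[:half]).value
        c_b = measure(seq[half:]).value
        frac = abs(c_a - c_b) / ((c_a + c_b) / 2.0)
        return UncertaintyEstimate(value=frac * c_orig, fractional=frac,
                                   method=method, n_windows=2)
    if method == "substring_sample":
        w = L // 2
        n_windows = L - w + 1
        if L < 200:
            starts = range(n_windows)
        else:
            rng = np.random.default_rng(seed)
            starts = rng.choice(n_windows, size=min(n_samples, n_windows),
                                replace=False)
        values = np.array([measure(seq[s:s + w]).value for s in starts])
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        frac = sd / mean if mean > 0 else 0.0
        return UncertaintyEstimate(value=frac * c_orig, fractional=frac,
                                   method=method, n_windows=len(values),
                                   mean=mean, sd=sd)
    raise ValueError(f"unknown uncertainty method {method!r}")
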