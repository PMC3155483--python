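"""Core sequence containers, file I/O, symbolization and model-system generators.

A categorical time series is represented as a :class:`SymbolSequence` over an
explicit :class:`Alphabet`.  Real-valued trajectories from benchmark dynamical
systems (:func:`generate_model_system`) are coarse-grained to binary symbol
sequences with :func:`partition_by_median` before any symbolic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "SymbolSequence",
    "RealSeries",
    "read_symbol_sequence",
    "write_symbol_sequence",
    "partition_by_median",
    "generate_model_system",
    "generate_markov_dialog",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered collection of distinct symbol tokens.

    Tokens must be non-empty, contain no whitespace, and be pairwise distinct.
    """

    symbols: tuple

    def __init__(self, symbols: Iterable[str]):
        symbols = tuple(symbols)
        if len(symbols) < 1:
            raise ValueError("alphabet must contain at least one symbol")
        seen = set()
        for s in symbols:
            if not isinstance(s, str) or not s:
                raise ValueError(f"invalid token {s!r}: tokens must be non-empty strings")
            if any(ch.isspace() for ch in s):
                raise ValueError(f"invalid token {s!r}: tokens must not contain whitespace")
            if s in seen:
                raise ValueError(f"duplicate token {s!r} in alphabet")
            seen.add(s)
        object.__setattr__(self, "symbols", symbols)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self) -> dict:
        """Token -> integer position map."""
        return {s: i for i, s in enumerate(self.symbols)}

    def __contains__(self, token: str) -> bool:
        return token in set(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


BINARY = Alphabet(("0", "1"))


@dataclass
class SymbolSequence:
    """Ordered categorical tokens over an explicit alphabet.

    Parameters
    ----------
    tokens : sequence of str
        The message, in order.  Every token must belong to ``alphabet``.
    alphabet : Alphabet, optional
        Declared symbol set.  When omitted, the alphabet is the distinct
        tokens in order of first appearance.
    metadata : mapping, optional
        Session-level metadata; recognised keys include ``session_id`` and
        ``duration_minutes``.
    """

    tokens: tuple
    alphabet: Alphabet
    metadata: dict = field(default_factory=dict)

    def __init__(self, tokens: Sequence[str], alphabet: Optional[Alphabet] = None,
                 metadata: Optional[Mapping] = None):
        tokens = tuple(tokens)
        if len(tokens) < 1:
            raise ValueError("a symbol sequence must contain at least one token")
        if alphabet is None:
            seen: dict = {}
            for t in tokens:
                seen.setdefault(t, None)
            alphabet = Alphabet(seen.keys())
        else:
            members = set(alphabet.symbols)
            for pos, t in enumerate(tokens, start=1):
                if t not in members:
                    raise ValueError(
                        f"token {t!r} at position {pos} is not in the alphabet")
        self.tokens = tokens
        self.alphabet = alphabet
        self.metadata = dict(metadata) if metadata else {}

    @property
    def length(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, item):
        if isinstance(item, slice):
            return SymbolSequence(self.tokens[item], self.alphabet, self.metadata)
        return self.tokens[item]

    @property
    def duration_minutes(self):
        return self.metadata.get("duration_minutes")

    def observed_alphabet(self) -> Alphabet:
        """Alphabet restricted to tokens that actually occur, in declared order."""
        present = set(self.tokens)
        return Alphabet(tuple(s for s in self.alphabet.symbols if s in present))

    def __repr__(self):
        head = " ".join(self.tokens[:8])
        tail = " ..." if len(self.tokens) > 8 else ""
        return f"SymbolSequence(L={len(self.tokens)}, N_alpha={self.alphabet.size}: {head}{tail})"


@dataclass
class RealSeries:
    """Real-valued series plus generator provenance (name, params, seed)."""

    values: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("real series must contain finite values only")

    def __len__(self):
        return len(self.values)


def read_symbol_sequence(path, alphabet: Optional[Alphabet] = None) -> SymbolSequence:
    """Read a whitespace-separated symbol file.

    Lines beginning with ``#`` are comments; a comment of the form
    ``# duration_minutes: 60`` declares the session duration.  Token positions
    in error messages are 1-based.
    """
    metadata: dict = {}
    tokens: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    val = val.strip()
                    if key == "duration_minutes":
                        metadata[key] = float(val)
                    elif key:
                        metadata[key] = val
                continue
            tokens.extend(stripped.split())
    if not tokens:
        raise ValueError(f"no symbols found in {path}")
    if alphabet is not None:
        members = set(alphabet.symbols)
        for pos, t in enumerate(tokens, start=1):
            if t not in members:
                raise ValueError(
                    f"token {t!r} at position {pos} is not in the supplied alphabet")
    return SymbolSequence(tokens, alphabet, metadata)


def write_symbol_sequence(seq: SymbolSequence, path, per_line: int = 40) -> None:
    """Write a symbol sequence in the whitespace-separated file format."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in sorted(seq.metadata.items()):
            fh.write(f"# {key}: {val}\n")
        toks = seq.tokens
        for i in range(0, len(toks), per_line):
            fh.write(" ".join(toks[i:i + per_line]) + "\n")


def partition_by_median(series: RealSeries) -> SymbolSequence:
    """Binary symbolization about the median of the full series.

    A value maps to ``'0'`` if it is strictly below the median and to ``'1'``
    if it is greater than or equal to the median (the median of an even-length
    series is the midpoint of the two central order statistics).
    """
    values = np.asarray(series.values, dtype=float)
    if len(values) < 2:
        raise ValueError("median partition requires a series of length >= 2")
    med = float(np.median(values))
    tokens = tuple("1" if v >= med else "0" for v in values)
    meta = {"partition": "median", "median": med}
    meta.update({k: v for k, v in series.source.items() if k == "name"})
    return SymbolSequence(tokens, BINARY, meta)


# ---------------------------------------------------------------------------
# Model systems
# ---------------------------------------------------------------------------

_ROSSLER_DEFAULTS = {"a": 0.2, "b": 0.2, "c": 5.7}
_LORENZ_DEFAULTS = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}
_HENON_DEFAULTS = {"a": 1.4, "b": 0.3}

#: sampling interval for the continuous systems
_SAMPLE_STEP = 0.1
#: internal RK4 substeps per sample (stability of the stiffer Lorenz flow)
_SUBSTEPS = 5
#: transient steps/iterates discarded before sampling
_TRANSIENT = 1000


def _rk4_sample(deriv, state, n_points, transient):
    """Classical RK4 with fixed sampling interval 0.1; returns x-coordinates."""
    h = _SAMPLE_STEP / _SUBSTEPS
    out = np.empty(n_points)
    step_index = 0
    for i in range(transient + n_points):
        for _ in range(_SUBSTEPS):
            k1 = deriv(state)
            k2 = deriv(state + 0.5 * h * k1)
            k3 = deriv(state + 0.5 * h * k2)
            k4 = deriv(state + h * k3)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        step_index += 1
        if not np.all(np.isfinite(state)):
            raise ArithmeticError(
                f"integration diverged (non-finite state) at step {step_index}")
        if i >= transient:
            out[i - transient] = state[0]
    return out


def generate_model_system(name: str, n_points: int, seed: int,
                          params: Optional[Mapping] = None) -> RealSeries:
    """Generate a benchmark real-valued series.

    Supported systems: ``constant``, ``rossler``, ``lorenz`` (autonomous ODEs
    sampled every 0.1 time units on the x-coordinate after a 1000-sample
    transient), ``henon`` (x-iterates after a 1000-iterate transient) and
    ``random`` (iid uniform on [0, 1]).  The seed perturbs the initial
    condition of the deterministic systems (scale 1e-6) so that independent
    realizations can be drawn; output is fully determined by
    ``(name, params, seed, n_points)``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    name_l = name.lower()
    source = {"name": name_l, "seed": int(seed), "n_points": int(n_points)}

    if name_l == "constant":
        value = float(params.get("value", 0.0))
        values = np.full(n_points, value)
        source["params"] = {"value": value}
    elif name_l == "random":
        values = rng.uniform(0.0, 1.0, size=n_points)
        source["params"] = {}
    elif name_l == "henon":
        p = {**_HENON_DEFAULTS, **params}
        a, b = float(p["a"]), float(p["b"])
        x = float(p.get("x0", 0.0)) + rng.normal(scale=1e-6)
        y = float(p.get("y0", 0.0)) + rng.normal(scale=1e-6)
        values = np.empty(n_points)
        for i in range(_TRANSIENT + n_points):
            x, y = 1.0 - a * x * x + y, b * x
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ArithmeticError(f"iteration diverged at step {i + 1}")
            if i >= _TRANSIENT:
                values[i - _TRANSIENT] = x
        source["params"] = {"a": a, "b": b}
        source["transient"] = _TRANSIENT
    elif name_l == "rossler":
        p = {**_ROSSLER_DEFAULTS, **params}
        a, b, c = float(p["a"]), float(p["b"]), float(p["c"])

        def deriv(s):
            x, y, z = s
            return np.array([-y - z, x + a * y, b + z * (x - c)])

        state = np.array([1.0, 1.0, 1.0]) + rng.normal(scale=1e-6, size=3)
        values = _rk4_sample(deriv, state, n_points, _TRANSIENT)
        source["params"] = {"a": a, "b": b, "c": c}
        source.update({"transient": _TRANSIENT, "sample_step": _SAMPLE_STEP,
                       "integrator": "rk4", "substeps": _SUBSTEPS})
    elif name_l == "lorenz":
        p = {**_LORENZ_DEFAULTS, **params}
        sigma, rho, beta = float(p["sigma"]), float(p["rho"]), float(p["beta"])

        def deriv(s):
            x, y, z = s
            return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

        state = np.array([1.0, 1.0, 1.0]) + rng.normal(scale=1e-6, size=3)
        values = _rk4_sample(deriv, state, n_points, _TRANSIENT)
        source["params"] = {"sigma": sigma, "rho": rho, "beta": beta}
        source.update({"transient": _TRANSIENT, "sample_step": _SAMPLE_STEP,
                       "integrator": "rk4", "substeps": _SUBSTEPS})
    else:
        raise ValueError(f"unknown model system {name!r}")

    return RealSeries(values, source)


# ---------------------------------------------------------------------------
# Synthetic coded-dialog generator
# ---------------------------------------------------------------------------

def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (principal left
    eigenvector, normalized)."""
    matrix = np.asarray(matrix, dtype=float)
    vals, vecs = np.linalg.eig(matrix.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_markov_dialog(transition: np.ndarray, alphabet: Alphabet,
                           length: int, seed: int,
                           start: Optional[str] = None,
                           metadata: Optional[Mapping] = None) -> SymbolSequence:
    """Sample a first-order Markov chain over ``alphabet``.

    ``transition`` is row-stochastic (rows sum to 1 within 1e-9).  The first
    token is ``start`` when given, otherwise it is drawn from the stationary
    distribution of the chain.  Output is reproducible given the seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    T = np.asarray(transition, dtype=float)
    if T.shape != (alphabet.size, alphabet.size):
        raise ValueError(
            f"transition matrix shape {T.shape} does not match alphabet size {alphabet.size}")
    row_sums = T.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > 1e-9)[0]
    if bad.size:
        sym = alphabet.symbols[bad[0]]
        raise ValueError(
            f"transition row for symbol {sym!r} sums to {row_sums[bad[0]]:.12f}, not 1")

    rng = np.random.default_rng(seed)
    n = alphabet.size
    if start is None:
        pi = stationary_distribution(T)
        current = int(rng.choice(n, p=pi))
    else:
        if start not in alphabet:
            raise ValueError(f"start token {start!r} is not in the alphabet")
        current = alphabet.index()[start]

    # cumulative rows + searchsorted: one uniform draw per step
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    draws = rng.random(length - 1)
    states = np.empty(length, dtype=np.intp)
    states[0] = current
    for i in range(1, length):
        current = int(np.searchsorted(cum[current], draws[i - 1], side="right"))
        states[i] = current
    tokens = tuple(alphabet.symbols[s] for s in states)
    meta = dict(metadata or {})
    meta.setdefault("generator", "markov_dialog")
    meta.setdefault("seed", int(seed))
    return SymbolSequence(tokens, alphabet, meta)
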