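"""Session-level analysis reports composing the full symbolic-dynamics
pipeline: frequencies, repeated n-grams, both complexity measures with rates,
quarter profiles, normalization, surrogate null tests, mutual-information and
entropy profiles.  Reports are deterministic given (input, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .grammar import complexity_uncertainty, grammar_complexity
from .information import compare_mi_profiles, entropy_profile, shifted_self_information
from .lempel_ziv import lz_complexity
from .ngrams import repeated_ngrams, symbol_frequencies
from .sequences import (SymbolSequence, generate_model_system,
                        partition_by_median, write_symbol_sequence)
from .surrogates import (complexity_generation_rate, normalized_complexity,
                         quarter_profile, surrogate_test)

logger = logging.getLogger("symdyn")

MEASURES = {"grammar": grammar_complexity, "lempel_ziv": lz_complexity}


@dataclass
class ReportConfig:
    """Analysis configuration; defaults match the package's reference study
    settings (499 surrogates, shifts to K=24, entropies to n=5, 1% n-gram
    report threshold, one-hour sessions)."""

    n_surr: int = 499
    k_max: int = 24
    n_max: int = 5
    pair_threshold: float = 0.01
    triple_threshold: float = 0.01
    seed: int = 0
    duration_minutes: float | None = None
    measures: tuple = ("grammar", "lempel_ziv")
    surrogate_kinds: tuple = ("equiprobable", "markov")
    full_alphabet: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ReportConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.measures = tuple(cfg.measures)
        cfg.surrogate_kinds = tuple(cfg.surrogate_kinds)
        return cfg


@dataclass
class SessionReport:
    """Aggregated per-session results; ``data`` is a JSON-ready nested dict
    with a config snapshot and every seed recorded."""

    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)

    def write(self, out_dir) -> Path:
        """Write report.json plus CSV side-files; returns the bundle path."""
        import pandas as pd
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        pd.DataFrame(self.data["frequencies"]).to_csv(
            out / "frequencies.csv", index=False)
        pd.DataFrame(self.data["repeated_pairs"]).to_csv(
            out / "repeated_pairs.csv", index=False)
        pd.DataFrame(self.data["repeated_triples"]).to_csv(
            out / "repeated_triples.csv", index=False)
        pd.DataFrame(self.data["mutual_information"]["profile"]).to_csv(
            out / "mi_profile.csv", index=False)
        pd.DataFrame(self.data["entropy"]["profile"]).to_csv(
            out / "entropy_profile.csv", index=False)
        return out


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_session_report(seq: SymbolSequence, config: ReportConfig) -> SessionReport:
    """Full analysis of one coded session."""
    L = len(seq)
    duration = config.duration_minutes or seq.duration_minutes
    if duration is None:
        raise ValueError(
            "session duration is required for rates: supply duration_minutes in "
            "the config or a '# duration_minutes:' line in the session file")

    freq = symbol_frequencies(seq)
    pairs = repeated_ngrams(seq, 2, config.pair_threshold) if L >= 2 else None
    triples = repeated_ngrams(seq, 3, config.triple_threshold) if L >= 3 else None

    rng = np.random.default_rng(config.seed)
    complexity_section = {}
    for name in config.measures:
        measure = MEASURES[name]
        result = measure(seq)
        delta = complexity_uncertainty(seq, measure, seed=config.seed).value \
            if L >= 4 else 0.0
        norm = normalized_complexity(
            seq, measure, n_surr=config.n_surr,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            full_alphabet=config.full_alphabet)
        p_null = {}
        for kind in config.surrogate_kinds:
            test = surrogate_test(seq, measure, surrogate_kind=kind,
                                  n_surr=config.n_surr,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)),
                                  full_alphabet=config.full_alphabet)
            logger.info("surrogate ensemble: measure=%s kind=%s n_surr=%d seed=%d",
                        name, kind, test["n_surr"], test["seed"])
            p_null[kind] = test
        quarters = quarter_profile(seq, duration, measure,
                                   n_surr=config.n_surr,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))
        complexity_section[name] = {
            "value": result.value,
            "bits": result.bits,
            "delta": delta,
            "rate_bits_per_min": complexity_generation_rate(result, duration),
            "normalized": asdict(norm),
            "p_null": p_null,
            "quarters": [{"rate": q.rate, "c_n": q.normalized.c_n,
                          "delta_c_n": q.normalized.delta_c_n}
                         for q in quarters],
        }

    mi = shifted_self_information(seq, min(config.k_max, L - 1))
    ent = entropy_profile(seq, min(config.n_max, L))
    for n, ok in zip(ent.orders, ent.good_statistics):
        if not ok:
            logger.warning("good-statistics criterion fails for n=%d "
                           "(expected count %.3g < 10): H_%d is length-limited",
                           n, ent.expected_counts[n - 1], n)

    data = {
        "session": {
            "id": seq.metadata.get("session_id"),
            "length": L,
            "duration_minutes": duration,
            "alphabet_size": seq.alphabet.size,
            "alphabet": list(seq.alphabet.symbols),
        },
        "frequencies": freq.to_frame().to_dict(orient="records"),
        "repeated_pairs": pairs.to_frame().to_dict(orient="records") if pairs else [],
        "repeated_triples": triples.to_frame().to_dict(orient="records") if triples else [],
        "complexity": complexity_section,
        "mutual_information": {
            "k_max": int(mi.shifts.max()),
            "dof": mi.dof,
            "profile": mi.to_frame().to_dict(orient="records"),
        },
        "entropy": {
            "limit_log2_L": ent.limit,
            "profile": ent.to_frame().to_dict(orient="records"),
        },
        "config": {**asdict(config), "measures": list(config.measures),
                   "surrogate_kinds": list(config.surrogate_kinds),
                   "duration_minutes": duration},
    }
    return SessionReport(data=_jsonify(data))


def run_compare(report_a: SessionReport, report_b: SessionReport,
                k_range: range | None = None) -> dict:
    """Between-session comparison: per-measure complexity-rate differences and
    a paired t-test on the mutual-information profiles."""
    from .information import MIProfile

    def profile_of(report):
        recs = report.data["mutual_information"]["profile"]
        return MIProfile(shifts=np.array([r["K"] for r in recs]),
                         values=np.array([r["I_bits"] for r in recs]),
                         chi2=np.array([r["chi2"] for r in recs]),
                         dof=report.data["mutual_information"]["dof"],
                         p_values=np.array([r["p"] for r in recs]))

    pa, pb = profile_of(report_a), profile_of(report_b)
    if k_range is None:
        if pa.shifts.max() != pb.shifts.max():
            raise ValueError("reports cover different shift ranges; "
                             "pass an explicit k_range")
        k_range = range(int(pa.shifts.max()) + 1)
    comparison = compare_mi_profiles(pa, pb, k_range)

    rates = {}
    for name in report_a.data["complexity"]:
        if name in report_b.data["complexity"]:
            ra = report_a.data["complexity"][name]["rate_bits_per_min"]
            rb = report_b.data["complexity"][name]["rate_bits_per_min"]
            rates[name] = {"rate_a": ra, "rate_b": rb, "difference": rb - ra}
    return _jsonify({
        "rates": rates,
        "mi_paired_t": asdict(comparison),
        "k_range": [min(k_range), max(k_range)],
    })


def run_simulate(kind: str, params: dict, seed: int, out_path) -> dict:
    """Generate a synthetic symbol-sequence file plus provenance JSON.

    ``kind`` is ``markov_dialog`` or a model-system name (``constant``,
    ``rossler``, ``lorenz``, ``henon``, ``random``; model series are
    median-partitioned to binary symbols).
    """
    params = dict(params or {})
    out_path = Path(out_path)
    if kind == "markov_dialog":
        seq = datasets.synthetic_session(
            length=int(params.get("length", 317)), seed=seed,
            duration_minutes=float(params.get("duration_minutes", 60.0)),
            persistence=float(params.get("persistence", 0.2)))
        provenance = {"kind": kind, "seed": int(seed),
                      "params": {"length": len(seq),
                                 "persistence": seq.metadata["persistence"]}}
    elif kind in ("constant", "rossler", "lorenz", "henon", "random"):
        n_points = int(params.pop("n_points", params.pop("length", 1000)))
        series = generate_model_system(kind, n_points, seed, params or None)
        seq = partition_by_median(series)
        provenance = {"kind": kind, "seed": int(seed), "source": series.source}
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    write_symbol_sequence(seq, out_path)
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    prov_path.write_text(json.dumps(_jsonify(provenance), indent=2, sort_keys=True))
    return {"sequence": str(out_path), "provenance": str(prov_path),
            "length": len(seq)}
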