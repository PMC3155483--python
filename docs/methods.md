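# Methods

This note documents the models, estimators, defaults and numerical
conventions behind `symdyn`, and what the synthetic-data generator does and
does not emulate.

## Grammar complexity

A message is compressed into an instruction set (main body + ordered
productions) by a fixed three-phase schedule:

1. **Pairs.** Count non-overlapping occurrences (greedy, left-to-right,
   counted per distinct pair across the main body and every production body;
   occurrences never span a body boundary).  While the most frequent pair
   occurs ≥ 3 times, replace all its counted occurrences with a fresh
   nonterminal and record the production, recounting after every
   replacement.  A pair occurring only twice is not replaced: the
   production's two body symbols exactly cancel the saving.
2. **n-tuples, n = 3, 4, ….** Replace the most frequent n-tuple occurring
   ≥ 2 times (for n ≥ 3 a replacement pays even at two occurrences),
   recounting at the same order until no repeat remains.  Two non-overlapping
   occurrences of an (n+1)-tuple contain two non-overlapping occurrences of
   its n-prefix, so the first order with no repeats exhausts the search.
3. **Exponents.** Every maximal run of k ≥ 2 identical items (terminal or
   nonterminal) becomes `item^k`, in the main body and production bodies.

**Accounting.** Each item in the main body and in production bodies costs 1;
an exponent k adds log₂(k); production left-hand sides and separators are
free.  The real-valued total is kept for downstream arithmetic (rates,
normalization); the integer part is the displayed bit value.  This accounting
is calibrated against the packaged worked example, whose compression yields
productions `α = A D`, `β = B C`, `γ = B^2 D` and a total of 27.585 (27
bits); the blocked companion message scores 20 bits.

**Determinism.** Ties among equally frequent candidates are broken by the
leftmost first occurrence (main body first, then productions in creation
order), which is unique.  Replacement substitutes exactly the greedily
counted occurrences.  The measure is an upper bound: no claim of minimality
is made, and none is needed for comparative use.

## Lempel-Ziv complexity

The 1976 phrase-counting definition: the first phrase is the first symbol;
each later phrase grows while it remains a substring of everything consumed
so far plus the candidate minus its last symbol, and closes with the first
violating symbol; the terminal phrase may close while still in the
vocabulary.  `C_LZ` is the phrase count.  Tokens are mapped to single unicode
code points so the substring test runs at C speed; the implementation is
verified exhaustively against a definition-level oracle on all binary
messages up to length 10.

## Surrogates and hypothesis tests

- **Equiprobable**: iid uniform over the alphabet.  By default the alphabet
  is restricted to symbols actually observed in the message (a declared
  22-code alphabet may contain codes that never occur); a flag restores the
  full declared alphabet, and a degenerate observed alphabet (constant
  message) falls back to the declared one.
- **Markov**: constrained randomization preserving length, first symbol and
  the *exact* pair-count matrix, via Hierholzer's algorithm on the pair
  multigraph with seeded shuffling of every out-edge list.  The original
  message is itself an Eulerian path, so a surrogate always exists; chain
  re-simulation (which preserves `[P_IJ]` only in expectation) is
  deliberately not used.
- **Shuffle**: a uniform permutation, provided for contrast only.
  Normalization against shuffles is refused: a constant message's shuffles
  equal itself, forcing `C_N = 1` where near-zero is the meaningful answer.

`P_NULL = (1 + #{C_s ≤ C_orig})/(1 + N_SURR)`; the original is counted in
the numerator, the minimum is `1/(1 + N_SURR)`, and ties count against
rejection.  Because complexity values are discrete, this convention makes
`P_NULL` *conservative* (stochastically above uniform) under the true null;
the tie-randomized rank is exactly uniform on its grid.  Both properties are
tested.  The Barnard–Hope criterion (reject iff `C_orig` is strictly below
every surrogate) is also provided.

**Uncertainties.** `ΔC_ORIG` comes either from the half-split (difference of
half-message complexities as a fraction of their average — zero when the
halves agree, a documented aberrant case) or from the mean and standard
deviation of window complexities at length `L//2` (all windows for L < 200,
else 100 seeded random windows).  `ΔC_N` propagates `ΔC_ORIG` and the
surrogate-distribution standard deviation in quadrature; the propagation
lives in one routine for easy amendment.

## Information-theoretic estimators

Plug-in (maximum-likelihood) estimators throughout, base-2, with 0·log 0 = 0;
`block_entropy` accepts an alternative estimator callable for bias-corrected
variants.  Shifted self-information pairs `(A_i, A_{i+K})` for
i = 1 … L − K.  The χ² independence test takes expected counts from the
contingency table's own margins, skips zero-expectation cells, and uses
`ν = (N_α − 1)²` with the *declared* alphabet size, per the measure's
definition; `p = Q(ν/2, χ²/2)` via the χ² survival function.

Finite-sample caveats, made explicit rather than hidden: plug-in `H_n`
saturates toward log₂(L) as n grows, and the changing window denominator
L − n + 1 can produce O(10⁻³) violations of `H_{n+1} ≥ H_n` in the saturated
regime.  The good-statistics flag `⟨N_i⟩ = (L − n + 1)/N_α^n ≥ 10` marks the
orders a message can support (a 317-symbol, 22-code session supports only
n = 1); session reports log a warning for orders beyond it.

## Model systems

Rössler (a = b = 0.2, c = 5.7) and Lorenz (σ = 10, ρ = 28, β = 8/3) are
integrated with classical RK4 at sampling interval 0.1 (five internal
substeps of 0.02 keep the stiffer Lorenz flow in the stability region;
symbolization at the 0.1 sampling grid is what matters).  Hénon uses
a = 1.4, b = 0.3 from the origin.  The first 1000 samples/iterates are
discarded so statistics are on-attractor.  Seeds perturb deterministic
initial conditions at scale 10⁻⁶ to allow independent realizations; all
generators are bitwise reproducible from (name, params, seed, n).  Series
are binarized about the **median** of the full series (values ≥ median map
to '1'); the median, not the mean, avoids false-positive structure in random
data.  These choices reproduce the reference behaviour: complexity ordering
constant < Rössler < Lorenz < Hénon < random at L = 1000 for both measures,
and a grammar/LZ Pearson correlation ≈ .998 over the four non-constant
systems at L = 1000 … 10000.

## Synthetic coded sessions

Real coded therapy sessions are not distributable, so the generator emulates
their surface statistics: a 22-code utterance alphabet, session lengths of
roughly 317–713 symbols per hour, and marginal code frequencies fixed to the
packaged combined-session table.  The chain is
`T = p·I + (1 − p)·1πᵀ` with π the packaged marginals and diagonal
persistence p = 0.2 (modest topic perseveration); both component kernels
leave π invariant, so marginals match the table exactly in expectation at
any persistence.  What this generator does **not** emulate: higher-order
syntax of dialog, speaker-turn constraints, non-stationarity within a
session.  Passing tests therefore validate the *measures* (a first-order
chain must fail to reject its own Markov null, as it does) — they do not
certify behaviour on real clinical structure beyond first order.

The χ²-goodness-of-fit check of generated marginals uses a lag-5 thinned
subsample: serial correlation (0.2⁵ ≈ 3·10⁻⁴ after thinning) would otherwise
inflate the statistic by (1 + p)/(1 − p).

## Problem sizes and defaults

Defaults mirror the reference analysis: N_SURR = 499, shifts K = 0 … 24,
entropy orders n ≤ 5, 1% report threshold for repeated n-grams, 60-minute
sessions.  The test suite and the acceptance script choose sizes that keep
statistical resolution while staying light: flatness of `C_N` across
L = 1000 … 10000 is checked with the Lempel-Ziv measure and 30 surrogates;
Markov-null self-consistency with 50 replicates of length-317 chains and 99
surrogates; the null-distribution study with 500 replicates at N_SURR = 19.
Transition-matrix recovery bounds follow binomial row-occupancy arithmetic:
0.01 elementwise is meaningful for a 2-state chain at L = 10⁵ (≈ 5·10⁴
visits/row) but not for 22-state chains, where per-cell bounds scale with
√(p(1−p)/visits).

## Known limitations

- Grammar complexity is an upper bound from one fixed schedule; alternative
  replacement orders can yield smaller instruction sets.
- Plug-in entropies and MI are biased upward at small L/N_α^n; the estimator
  slot accepts corrections but none ships enabled.
- The Eulerian-path surrogate sampler randomizes edge orders; it is not a
  proof-exact uniform sampler over all Eulerian paths, which is acceptable
  for rank-based tests.
- `C_N` of short blocks (L ≈ 100) of a constant message sits near 0.1 rather
  than 0: the surrogate mean is itself small at short lengths.
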