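# Methods

## Model

A document is treated as a bag of sentences. For a two-word query (A, B)
each sentence is one "perception trial" with four outcomes: it activates
concept A, concept B, both, or neither. Activation of concept *w* means
the sentence shares at least one word with the neighbor set O_w, the union
of the token sets of all sentences that contain *w* (stopwords removed,
the concept word itself always included). The trial counts N_ij define a
pure two-qubit state with amplitudes c_ij = √(N_ij/N)·e^{iφ_ij}; the
concurrence of that state, Q = 2|c01c10 − c00c11|, is the semantic
connection measure. The phases enter only through
Δ = φ01 + φ10 − φ00 − φ11, so the canonical phase assignment places the
whole of Δ on φ01 and zeros the rest; `concurrence_from_counts`,
`concurrence` on a built state, and the explicit spin-flip overlap
⟨Ψ|σ_y⊗σ_y|Ψ*⟩ are three computations of the same quantity and are
cross-tested to 1e-10.

Varying Δ sweeps Q over [q_min, q_max] with extremes at cos Δ = ±1:
q_min = 2|√(N01N10) − √(N00N11)|/N, q_max = 2(√(N01N10) + √(N00N11))/N.
The "phase-randomized" value q_rand = 2√(N01N10 + N00N11)/N implements
the statement that averaging over Δ nullifies the cosine cross-term; note
this closed form is the root-mean-square of Q over uniform Δ, not its
mean. The interval is degenerate whenever any count is zero.

The classical counterpart is the phi coefficient of the same 2×2 table.
It is undefined when a row or column marginal vanishes; we propagate NaN
as an explicit marker and defer the substitution policy (zero or drop) to
regression time. The benchmark regression uses the zero policy over all
15 documents; the drop policy (n = 12) is also exposed and gives a
visibly different R² (≈ 0.29 vs ≈ 0.46).

## Tokenization choices

Sentence units are split on runs of `. ! ?` followed by whitespace or end
of input — no abbreviation heuristics, since the measure only needs a
reproducible segmentation, and the rule is configurable
(`TokenizerConfig.delimiter`; `granularity="paragraph"` splits on blank
lines instead, the same model applies unchanged at coarser units). Tokens
are case-folded maximal runs of letters; digits and punctuation are
dropped. No stemming or lemmatization is applied by default, to avoid a
silent dependency on language resources. Stopwords are removed only when
building neighbor sets: with function words inside O_w nearly every
sentence would activate both concepts and the counts would saturate. The
packaged list has ~100 English function words; an empty list is allowed.
A concept absent from the document degenerates its neighbor set to the
concept word itself (with a warning), which zeroes the corresponding
counts and lets degenerate documents be scored 0 rather than fail.

## Phase tuning

The quantum phase gives each document one degree of freedom: its
concurrence may sit anywhere in [q_min, q_max]. `tune_concurrences`
jointly maximizes the determination coefficient R² (squared Pearson
correlation, direction-symmetric) of the per-document values against the
reference expert scores, subject to those box constraints. The optimizer
is deterministic coordinate ascent starting from the q_rand values:
documents are visited in fixed order; each coordinate's best response is
located by a 65-point grid scan followed by golden-section refinement in
the bracketing cell, because R² along one coordinate is the square of a
linear-over-root-quadratic ratio and can carry two local maxima, which a
single golden-section bracket can miss. Moves that would lower the
objective are rejected, so the achieved R² is monotone and never below
the q_rand baseline; sweeps continue until the gain per sweep falls below
1e-9, plus two confirmation sweeps. On 3-document instances the result
matches an exhaustive grid oracle; on the packaged benchmark it reaches
R² ≈ 0.843 from the 0.543 baseline.

## LSA baseline

Each document gets its own term-by-sentence matrix with log(1 + count)
weighting by default (raw counts optional); log damping is standard LSA
practice against burstiness. A truncated SVD with k = 12 (clipped to the
matrix rank for short documents) yields word vectors as
singular-value-scaled rows of U normalized to unit length, so the scalar
product of two word vectors is a cosine guaranteed to lie in [−1, 1]. A
query word missing from a document raises an error rather than silently
fabricating a similarity. Because the original study's exact weighting and
normalization are not recoverable, the benchmark table stores the original
per-document LSA values for the regression, while the LSA implementation
here is used for fresh documents.

## Synthetic corpora

The generator emulates the perception experiment directly rather than any
particular natural language: every sentence draws its class i.i.d. from a
joint table p_ij, receives 1–3 markers from a disjoint A-associate
vocabulary iff its class activates A (likewise for B), plus 3–12 filler
tokens from a third disjoint vocabulary. Defaults: p = (0.4, 0.3, 0.2,
0.1), 2000 sentences, 8 markers per concept, 120 filler types. Recovery
tests categorize generated corpora with the marker vocabularies as
neighbor sets (`GeneratorSpec.neighbor_sets()`), the ground truth of the
simulation; building neighbor sets from the generated text itself would
let fillers that co-occur with markers leak into O_w and bias the counts —
a real phenomenon in natural text that the generator deliberately does
not emulate. Passing recovery tests therefore validate the counting and
estimation machinery under known truth, not the behavior of neighbor-set
induction on real prose. Sentence lengths are bounded-uniform for
simplicity; real sentence-length distributions, topical drift, and
polysemy are out of scope.

Statistical test sizes were fixed in advance at the scales the claims are
stated for: parameter recovery uses 200 seeds at n = 2000 against
binomial 3σ bands (≥95% of runs must pass; the expected failure rate is
≈1%), the factorizable-table null uses 100 seeds at n = 5000 with mean
Q(Δ=0) < 0.05 (sampling noise scales as N^{-1/2} ≈ 0.014), and the
shuffle null compares 100 word-shuffles of a 300–400 sentence structured
corpus against its unshuffled value.

## Benchmark fixture

The packaged table holds the 15 probe web documents for the query
*website promotion*: mean expert score (0–10, 8 experts), phase-randomized
concurrence with its attainable interval (7 documents have non-degenerate
intervals), phi (undefined for 3 documents), search-engine rank (a
permutation of 1..15), and per-document LSA cosine. Three partially
garbled source rows are transcribed as (expert 4.8 / 3.9 / 1.9: q = 0,
phi undefined, ranks 10 / 11 / 15, LSA 0) — the unique reading under
which the ranks form a permutation and exactly three phi entries are
undefined. The file is checksummed at load. Expert relevance scores map
linearly to the concurrence scale (score/10); regressions use the mean
expert score directly, not its rank transform.

## Numerical notes

State and probability-table invariants are enforced at 1e-12; concurrence
requires the state norm within 1e-9. The factorization test uses the
cross-product form N01·N10 = N00·N11 (defined when denominators vanish)
with tolerance scaled by N². Small negative values under the concurrence
root from float cancellation are clamped to zero. Ranking ties preserve
input order; undefined phi ranks last. All randomness flows through
seeded `numpy.random.default_rng`.

## Limitations

Only pure states and exactly two concepts are modeled; no procedure infers
phases from text — Δ is exogenous, and tuning it against reference scores
is post-hoc fitting, not prediction. Neighbor sets are per document, so
scores are not comparable across corpora with very different vocabulary
overlap. The segmenter is deliberately naive about abbreviations, and the
default stopword list is English-only.
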