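# Methods

## Model

definition2vec is skip-gram with negative sampling (SGNS) in which the
target vector of term `w` is not a free parameter but the blend

```
U_w = ( √f_w · U′_w + β · z̄_w ) / ( √f_w + β ),    z̄_w = (1/m) Σ_{d ∈ D_w} z_d
```

with `f_w` the term's occurrence count in the training corpus, `D_w`
its cleaned definition of length `m` (occurrences counted with
multiplicity), `U′_w` a free per-term vector, `z_d` a shared
definition-word vector, and `β ≥ 0` the blending weight. Three
parameter tables are learned: `U′` (|V| × d), the context table `V`
(|V| × d), and `Z` (|D-vocab| × d).

The per-pair loss is the standard SGNS objective
`−log σ(U_t·V_c) − Σ_j log σ(−U_t·V_j)` over the context pair and its
`K` negatives. SGD updates are the chain rule through the blend: with
`g_x = σ(U_t·V_x) − label(x)` and `G = Σ_x g_x V_x` (all evaluated at
pre-step values),

- `V_x ← V_x − α g_x U_t` for the context and each negative,
- `U′_t ← U′_t − α G · √f_t /(√f_t + β)`,
- `z_d ← z_d − α G · β /(m(√f_t + β))` once per occurrence of `d` in `D_t`.

Only the *target's* definition words are updated; negatives contribute
through their `V` rows only.

Degenerate cases are defined exactly: a term with no definition, or
β = 0, uses `U_w = U′_w` verbatim (the update scale on `U′` is then 1
and `Z` is untouched); `f_w = 0` gives `U_w = z̄_w` verbatim, which is
also how out-of-vocabulary terms are embedded at query time; the
doubly-degenerate corner `f = 0, β = 0` (never reached in practice —
it requires a definition present but disabled) is defined as `U′_w`.

## Preprocessing

Raw text is split on whitespace; tokens are lowercased and stripped of
digits and punctuation (tokens left empty are dropped, so "7.2%"
vanishes and "A1C" becomes "ac"). Multi-word concepts are found by a
greedy left-to-right longest match against a user-supplied term
dictionary (span cap `max_len = 5` tokens) and joined with
underscores; unmatched tokens are removed, so a document becomes a
sequence of dictionary terms. This dictionary matcher is a deliberate,
transparent stand-in for a full concept-recognition engine: it
implements exactly the contract the model needs (multi-word → single
token, non-concept tokens dropped) without word-sense disambiguation.

Definitions come either from a two-column TSV (multiple rows per term
are concatenated in file order) or from pipe-delimited UMLS-style
MRCONSO/MRDEF files, joined per concept: every term string of a CUI
receives the concatenation of all definitions of all of that CUI's
AUIs (column positions are configurable; defaults match the standard
layouts). Definition text is cleaned with the same tokenizer, stop
words are removed (user-supplied list; a small built-in default
otherwise), and definition words occurring fewer than
`min_def_word_count = 2` times across all retained definitions are
dropped. The rare-word threshold is applied over the pooled
definitions of in-vocabulary terms, a corpus-level reading of "remove
rare words"; a definition-level threshold would delete nearly
everything at these definition lengths.

## Training

Hyperparameter defaults: window 5 (fixed radius, no random shrinking,
windows never cross document boundaries), dimension 100, learning rate
α = 0.01 (constant — no decay, no frequent-word subsampling), K = 5
negatives, 10 epochs, β = 10, `min_count` 1. Negatives are drawn from
unigram frequencies raised to `neg_exponent = 0.75` (1.0 gives the
literal corpus distribution) by inverse-CDF sampling, excluding the
current target and context; collisions are re-drawn. Initialisation:
`U′` and `Z` i.i.d. uniform on (−0.5/d, +0.5/d), `V` zero, all driven
by one seeded PCG64 generator; runs are bit-reproducible.

The composed vector is recomputed fresh at every step — `U′` and `Z`
change constantly, and correctness is preferred over caching.

The inner loop is a numba-compiled kernel that reproduces the per-pair
math of `sgd_step` exactly (a test drives the same random stream
through a literal Python loop of `sample_negatives` + `sgd_step` and
requires agreement to 1e-10 per coordinate). A second kernel,
`train_skipgram`, implements textbook SGNS directly — no composition,
free table read and updated in place — while drawing the identical
random stream; with β = 0 the two trainers are bit-identical, which is
both a regression test and the β = 0 reduction guarantee.

Per-epoch mean loss (summed pair losses per corpus position, averaged
over positions) is logged and returned; on every fixture the final
epoch's mean is at or below the first's.

## Synthetic data

The generator plants the signal alignment the model exploits: each
document belongs to one of `n_clusters` topics and draws its tokens
from that cluster's terms, so co-occurrence encodes cluster identity;
each term's definition draws ≥ 80% of its words from a cluster-private
definition vocabulary, so definitions encode the same identity.
Defaults (chosen once as a desk-scale caricature of a small clinical
corpus): 5 clusters × 20 terms, 400 documents × 50 tokens, geometric
frequency skew (ratio 0.7) over a cluster's frequent terms so the
√f weighting is exercised from ~1100 occurrences down to ~5, 20% of
each cluster's terms planted as rare with exact corpus counts of 1–2,
two held-out terms per cluster with definitions but zero occurrences,
5% shared noise tokens, definition length 8 over a cluster vocabulary
of 12 plus a shared pool of 10. Generated names are purely alphabetic
so they survive the digit-stripping cleaner. Everything is emitted in
the package's own file dialects and is byte-identical for a fixed
seed.

What this does *not* emulate: natural language word order and syntax,
polysemy, cross-topic documents, realistic definition prose, spelling
noise, or Zipfian vocabulary tails beyond the geometric skew. Passing
the recovery tests therefore shows the optimisation and the blend
behave as designed when context and definitions genuinely carry
cluster signal — not that any particular score would be reached on
real clinical text.

## Evaluation

- Nearest neighbours: cosine similarity, query excluded, ties broken
  lexicographically for determinism.
- Pair similarity: Pearson r between model cosine and human score;
  pairs with either term missing are skipped and the retained count is
  reported alongside r (coverage differs across benchmarks). Fewer
  than two retained pairs, or a constant series, is an error rather
  than a NaN.
- Clustering purity: k-means (k-means++ seeding, 10 restarts, fixed
  seed) on the labeled terms' vectors, scored by NMI normalized by the
  arithmetic mean of the entropies (min/geometric are available); the
  metric is invariant to cluster and label renaming.
- Geometry diagnostics: mean within-category minus between-category
  cosine ("margin"), per-category centroids, and nearest-centroid
  assignment, used for the rare/OOV probes.

## Numerical choices

σ is computed as a stable logistic (losses via `log1p`-style
`logaddexp`, never overflowing); pair losses are accumulated in
float64. Vocabulary ids are assigned in descending frequency with
lexicographic tie-breaks so builds are deterministic. The word2vec
text writer emits `repr` precision so write→read round-trips are
exact; checkpoints (one `.npz` archive holding the three tables, both
vocabularies, frequencies, definitions and the config) round-trip
exactly as well.

## Problem sizes

Tests and the acceptance script run the full pipeline on the standard
fixture above (20 000 tokens, 120-term vocabulary, d = 100, 10
epochs), three seeds × two β values; the gradient oracle checks 200
random small instances (d 3–8, K ∈ {1,5}, f ∈ {0,1,4,100},
β ∈ {0,2,10}, |D| ∈ {0,1,3}) against central finite differences at
h = 1e-6, requiring relative error < 1e-5 per parameter block.

## Known limitations

Single-threaded training only (determinism is favoured over hogwild
parallelism); no hierarchical softmax; no subword information, so an
OOV term without a definition has no embedding at all; the dictionary
matcher has no disambiguation, so ambiguous surface forms map to
whatever the dictionary says; β is global rather than per-term, which
is exactly the knob the blend's √f weighting is meant to soften.
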