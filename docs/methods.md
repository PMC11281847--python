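# Methods

## Problem and model

Entity linking (EL) maps an annotated text span (a *mention*) to a concept
code in a knowledge base (KB) defined by a gazetteer: a flat dictionary of
codes and surface terms, optionally extended with multilingual alias tables.
The pipeline follows the canonical generate-and-rank architecture, augmented
with one preprocessing stage aimed at *complex mentions* — spans of several
tokens that paraphrase a concept rather than naming it, and therefore share
little surface text with any KB alias.

### Candidate generation

Mentions and aliases are embedded as TF-IDF vectors over character 3-grams:

- grams are case-folded, cross token boundaries (internal spaces included,
  no boundary padding), and a string shorter than *n* contributes itself as
  a single gram;
- term frequency is the raw gram count; inverse document frequency is the
  smoothed `idf(g) = ln((1+A)/(1+df_g)) + 1`, with `A` the number of indexed
  aliases and `df_g` the number of aliases containing `g`; rows are L2
  normalized.

This is exactly the smooth-idf/L2 formulation of scikit-learn's
`TfidfVectorizer`, which implements the transform; only the analyzer is
custom (for the short-string rule). The formulation guarantees that a
mention identical to an alias has cosine exactly 1.0 — the "direct lookup"
case, which the confidence gate depends on. A concept's score is the
maximum cosine over its aliases (one good alias suffices for linking);
the top k = 64 concepts are returned, ties broken by higher sparse score
then lexicographically smaller code, so candidate lists are byte-stable.

The dense side of the ensemble is a contract: `retrieve(query, k)` plus
`score_pair(query, code)`, the latter defined for *every* pair so that
fusion can impute scores for union members. The shipped implementation is a
deterministic hashed-character embedder (CRC32 buckets of 3-gram counts, L2
normalized, cosines in [0,1]); an adapter for an external sentence encoder
implements the same contract. Fusion takes the per-code **maximum** across
retrievers: unlike averaging, this preserves the exact-match ⇒ 1.0 property
and never lowers any retriever's score.

### Confidence-gated simplification

A mention is routed to the simplifier when its top baseline confidence is
strictly below the threshold *t*; *t* ≥ 1.0 routes every mention, exact
matches included (the "simplify everything" configuration is conventionally
labelled t = 1.0). An empty candidate list counts as confidence 0 and is
always gated. The rewritten mention is retrieved again and its candidates
**replace** the baseline list; when the rewriter returns the input unchanged
the baseline list is kept, so do-nothing rewrites are free.

The threshold grid is 0.50–1.00 in steps of 0.05; the selected *t*
maximizes the recall@1 delta over the baseline, ties resolved toward the
smaller threshold (fewer backend calls). Because a mention's rewrite does
not depend on *t*, the sweep simplifies and re-retrieves each mention once
and reuses the outcome across grid points.

Whether gating should use the fused ensemble score or the sparse score
alone is a genuinely open choice; the pipeline gates on the top score of
whatever retriever it is given (the ensemble when one is configured), which
keeps the gate consistent with the candidates actually produced.

### Prompting and backends

The simplifier is a contract (`simplify(prompt) -> text`). The default
prompt is a few-shot template: an instruction, four in-context input/output
pairs fenced in triple backticks, and the query mention as a final fenced
input with an open output slot (9 fenced segments in total). Three examples
are drawn from *retrieval failures* — training mentions whose gold concept
is absent from the top-64 — each paired with the canonical name of its gold
concept; sampling is seeded and performed over sorted deduplicated mention
texts, so it is order-invariant. The fourth example is a fixed identity
demonstration ("disnea" → "disnea") showing that easily linkable mentions
should pass through unchanged.

Backends: `identity` (echo), `oracle` (a recorded mention → canonical-name
map, optionally with a seeded failure rate; used by the synthetic module),
and a generic HTTP chat-completion adapter (temperature 0, retries, API key
from the environment). All calls go through an append-only JSON Lines cache
keyed by SHA-256 of (backend id, template fingerprint, mention text), so a
prompt-altering change invalidates the cache while re-runs never re-invoke
the backend. Empty backend output falls back to the original mention with
`changed = false`; transport failures raise a typed error.

### Reranking

The reranker is a linear listwise model over per-candidate features:
retrieval score, character-3gram Jaccard between mention and best alias, an
exact-match flag, and the mention/alias token-length difference (capped at
8 and scaled to [0,1] so no feature dominates the shared learning rate).
Training minimizes listwise softmax cross-entropy of the gold candidate
(full-batch gradient descent from zero weights, 20 epochs, learning rate
1.0); after each epoch, accuracy on a validation set is measured and the
best-epoch weights are kept. Shortlists lacking their gold concept are
skipped. A `regularizer` hook accepts an additional penalty term; none is
used by default. Reranking emits a permutation of the final list — ties
fall back to the canonical retrieval order, making the output invariant to
input candidate order — so it can never change recall@64, only recall@1.

### Prediction

No NIL option: every mention receives exactly one code (hence recall@1 =
precision = accuracy). The single exception is a mention whose candidate
list is empty even after gating, which receives the reserved code
`UNMAPPABLE` with a logged warning.

## Evaluation suite

- `recall_at_k`: fraction of mentions with gold among the top
  `min(k, |list|)` candidates.
- `bin_by_confidence`: mentions binned by the *baseline* top confidence into
  `[0,0.5]`, `(0.5,0.6]`, …, `(0.9,1.0]`, and a singleton bin for exact 1.0
  (score ≥ 1 − 1e-9, since direct lookups are qualitatively distinct); the
  catch-all bottom bin exists because generated data can produce scores the
  clinical corpora did not. Bins are validated to be disjoint and
  exhaustive; counts always sum to the total.
- `impact_by_length`: per token-length stratum, the fraction of mentions
  whose gold *entered* the top-k only after simplification (gained) versus
  *left* it (lost), and — among mentions retrieved on both sides — strict
  rank improvements/degradations (equal ranks count as neither). The
  identity `Δrecall@k = Σ_L (gained_L − lost_L)·n_L / N` holds exactly and
  is asserted in tests. Lengths are reported unpooled; `pool_from` pools a
  tail of rare long mentions.
- `compare`: recall@k before/after with exact deltas.

## Synthetic data generator

The generator produces the statistical structure the method assumes, with
full determinism under a seed:

- **KB**: pseudo-word aliases built from CV syllables over a 12-consonant
  alphabet. Every concept owns a private pool of globally unique tokens;
  aliases are combinations of that pool, so alias strings never collide
  across concepts and the exact-match invariant is unambiguous. Canonical
  names have 1–3 tokens.
- **Simple mentions** (probability `1 − p_complex`): a KB alias verbatim,
  with optional per-character noise (`char_noise`, default 0). With zero
  noise they are direct lookups at confidence 1.0.
- **Complex mentions**: the canonical name's tokens, a random subset of
  which is paraphrased (resampled syllables), wrapped in 2–6 filler tokens;
  with probability `p_full_paraphrase` (default 0.5) *all* tokens are
  paraphrased. Filler tokens come from a disjoint 6-consonant alphabet, so
  they never collide with alias tokens and reliably depress confidence.
  Partially paraphrased mentions keep the gold concept retrievable at
  depressed confidence (spreading top scores over ≈0.2–0.95, which gives
  the threshold sweep a real gradient); fully paraphrased mentions share
  almost no grams with any alias, so the baseline generator genuinely
  misses the gold concept — the situation a mention like "aumento de
  densidad en lóbulo inferior" creates for a dictionary that only knows
  "lesión de pulmón". A literal light inflection of the alias would leave
  its grams inside the mention and the baseline would almost never miss,
  making recall@64 improvements unobservable.
- **Documents**: mentions are packed ~10 per document with exact character
  offsets, exercising the span validation of the corpus reader.
- **Oracle map**: every complex mention maps to its concept's canonical
  name; the oracle simplifier replays this map (with a seeded, per-mention
  deterministic failure rate). The *adversarial* variant additionally maps
  a fraction of simple mentions to a *wrong* concept's canonical name,
  modelling a rewriter that over-generalizes already-linkable mentions —
  this makes simplify-everything (t = 1.0) measurably worse than the
  selected threshold, the qualitative signature of over-gating.

What the generator does **not** emulate: real lexical statistics (Spanish
morphology, shared substrings between related concepts, ambiguous aliases),
annotation noise, and rewriter outputs that are near-misses rather than
exact canonical names. Passing tests therefore demonstrate the pipeline's
mechanics and its qualitative behaviour (gating monotonicity, recall
recovery, over-gating harm), not clinical-corpus performance levels.

## Default problem sizes

The property suite runs on a 60-concept / 200-mention dataset for unit
checks and a 1000-concept / 5000-mention benchmark (p_complex = 0.5,
char_noise = 0, oracle failure 0) for the end-to-end study; the same
benchmark backs `scripts/acceptance.py`. These sizes give stable fractions
(binomial standard error < 1 pp on 5000 mentions) while a full run stays in
the tens of seconds on one CPU.

## Numerical choices and degenerate inputs

- Scores are clamped to ≤ 1.0; equality-with-1.0 tests use a 1e-9
  tolerance (floating-point cosines of identical strings can land at
  1 ± 1e-16).
- Tie-breaks are total everywhere (score, then sparse score, then code;
  reranker ties by prior rank), so all outputs are reproducible
  byte-for-byte.
- A query sharing no known n-gram with the index returns an empty list,
  treated as confidence 0 downstream.
- Loading a gazetteer trims terms but preserves case (folding happens in
  the analyzer); rows with empty terms are dropped; duplicate
  (code, term, language) triples collapse to one alias.
- The validation split is by document, not mention, to prevent leakage of
  near-duplicate mentions across sides; the split unit is a deliberate
  design choice.

## Known limitations

- The reranker is a linear model over surface features; it demonstrates the
  training contract (listwise softmax, validation-accuracy checkpointing,
  permutation-only output) but is not a contextual cross-encoder and does
  not consume document context. A context-aware adapter would implement the
  same `score_list` interface and read the surrounding document text from
  the corpus it is given.
- The chat backend is exercised only against a local fake transport in
  tests; rate limiting and streaming responses are out of scope.
- Composite mentions (one span, several codes) are filtered out, not
  linked; NIL detection is deliberately absent.
- Alias-table merging is a generic set union; reproducing any particular
  terminology release's deduplication pipeline is out of scope.
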