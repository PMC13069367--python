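# Methods

`summdiv` quantifies how *personalized* a set of per-timeline summaries is.
The premise: a summarizer that produces generic, templated text will emit
summaries that resemble each other across timelines, while a summarizer that
truly reflects each timeline's idiosyncratic content will emit summaries that
differ. Within-system diversity is therefore used as a proxy for
personalization, measured at the surface (lexical) and semantic level, and
compared across systems with paired permutation tests.

## Data model

The unit of analysis is a summary keyed by `(timeline_id, system_id)`: one
summary of one user's post timeline by one summarization system (a human
expert or a model pipeline). A summary may carry three aspect paragraphs —
overall mental-state assessment, inter/intrapersonal patterns, changes over
time — whose newline-join must equal the full text. Likert ratings (integer
1–5) attach to `(timeline, system, criterion, rater)` with five criteria:
factual consistency, general usefulness, and aspect-specific usefulness for
each of the three aspects.

All statistics are invariant to record order in the input files; documents
are internally sorted by key.

## Surface diversity: self-ROUGE

For a system with *m* summaries, self-ROUGE is the mean pairwise ROUGE score
over all C(m, 2) unordered within-system pairs. Lower self-ROUGE = less
lexical overlap between a system's summaries = higher surface diversity.

Six variants are implemented from first principles (they are the point of the
package, not a wrapper):

| variant | overlap unit | denominators |
|---|---|---|
| rouge1/2/3 | clipped n-gram multiset intersection | gram counts of each text |
| rougeL | longest common subsequence (DP) | token counts of each text |
| rougeS2 | skip-bigrams, ≤ 2 intervening tokens | skip-bigram counts |
| rougeSU2 | count-wise union of unigrams and gap-2 skip-bigrams | union counts |

Numerical conventions, all recorded in report metadata:

* **Score component** — F-measure (β = 1). Precision and recall are
  asymmetric in the pair; F is symmetric, which is the only coherent choice
  for unordered within-system pairs. Both are retained on every
  `RougeScore` for audit.
* **Clipped counting** — per-gram overlap is `min(count_a, count_b)`,
  the standard ROUGE convention.
* **Gap semantics** — "gap of up to 2 words" means at most 2 *intervening*
  tokens (`j − i − 1 ≤ 2`); `extract_skip_bigrams` exposes `max_gap` so the
  window-based alternative is one argument away. `max_gap = 0` degenerates
  to contiguous bigrams.
* **Tokenizer** — lowercase; tokens are maximal alphanumeric runs with
  word-internal apostrophes kept; no stemming, no stopword removal. Minimal
  preprocessing maximizes reproducibility; the tokenizer is a plain function
  and can be swapped at the call sites that accept token sequences.
* A zero denominator (empty gram multiset) yields precision/recall 0 by
  definition; F is 0 whenever P + R = 0.

`SelfRougeResult.per_summary_link` maps each timeline to the mean score of
its summary against all others in the system. Its mean equals the overall
value (each pair appears in exactly two links), and it is the per-summary
unit over which effect sizes are computed.

## Semantic diversity: mean centroid similarity

Summaries are embedded, embeddings are unit-normalized on ingestion, the
centroid is their componentwise arithmetic mean (not re-normalized), and the
statistic is the mean cosine similarity of the embeddings to that centroid.
Lower = more semantically diverse. Normalization makes the statistic
scale-free and the centroid a spherical mean direction; the value is
invariant to any common orthogonal rotation and to summary order, and for
unit vectors it is ≤ 1 with equality iff all embeddings coincide. Degenerate
geometry — a zero-norm embedding, or a zero centroid (e.g. an antipodal
pair) — raises an error naming the offending timeline rather than returning
a silent 0/0.

Embedders are plugins behind a contract (deterministic, fixed dimension,
finite values) keyed by string id. The bundled `reference` embedder is a
hashed bag-of-words encoder: each token is hashed with BLAKE2b into one of
`dim = 64` buckets, counts accumulate, and the vector is unit-normalized. It
is deterministic across platforms, needs no model download, and captures
exactly lexical-content geometry — two texts with disjoint vocabulary are
near-orthogonal, identical texts coincide. 64 buckets keep hash collisions
rare at the synthetic vocabulary's size while staying fast. Transformer
sentence encoders can be registered with `register_embedder` and flow
through the identical centroid machinery; nothing in the package or its
tests requires one.

## Inference: paired permutation tests and Cohen d

Each timeline contributes one summary per system, so under the null the two
system labels are exchangeable within a timeline. The test swaps the two
summaries of each timeline independently with probability 1/2 and recomputes
the group statistic difference; `B = 1000` permutations by default.
Conventions:

* two-sided: permutations count when `|perm diff| ≥ |obs diff|`;
* Monte-Carlo p uses add-one smoothing `(r + 1)/(B + 1)`, so p is never 0
  and never below `1/(B+1)`; the exhaustive mode (all `2^n` assignments,
  refused above n = 20) reports the raw proportion, which is positive
  because the identity assignment always counts;
* fixed seed ⇒ bit-identical results; grid rows derive per-row seeds from
  the root seed and row labels, so adding a pair or metric to a report never
  perturbs existing rows.

Cohen d is `(mean_a − mean_b) / pooled SD` with sample (n−1) variances. The
unit of observation is a deliberate convention, recorded in output metadata:
per-summary link scores for self-ROUGE, per-summary centroid similarities
for semantic diversity, per-timeline rater-mean scores for ratings. Zero
pooled variance is an `UndefinedEffectError`; the ratings and grid paths
report it as d = 0 with a `degenerate_effect` flag rather than failing an
otherwise valid comparison.

For the diversity grid, recomputing self-ROUGE from scratch inside every
permutation would be O(B · m²) ROUGE evaluations; instead the pairwise score
matrix over the union of both systems' summaries (2n × 2n) is computed once
and every permuted group statistic is a submatrix mean. This is an exact
reformulation, not an approximation.

Ratings aggregation averages raters within `(timeline, system, criterion)`
before testing, because per-timeline pairing is the only pairing structure
in the design; the per-system mean then averages per-timeline means. No
multiple-testing correction is applied by default.

## Synthetic data generator

Real clinical summary corpora of this kind cannot be redistributed, so the
generator produces structurally faithful stand-ins from bundled, hand-written
neutral word lists (no real user content): a paired-complete
(timeline × system) grid of three-paragraph summaries, each paragraph built
from sentence templates themed on one clinical aspect.

Per-system dials and what they emulate:

* `template_pool_size` (1–20, default 6) — template reuse; small pools model
  generic, repetitive systems. Self-ROUGE is non-increasing in pool size in
  expectation.
* `synonym_rate` (default 0.15) — per-token probability of swapping a
  template word for a thesaurus synonym; raises lexical variety at constant
  structure. Self-ROUGE is decreasing in this rate.
* `personal_token_rate` (default 0.3) — per-sentence probability of
  inserting a timeline-specific content token (a unique hobby/topic noun per
  timeline); models idiosyncratic, personalized content. Centroid similarity
  is non-increasing in this rate under the reference embedder.
* `sentences_per_aspect` (default 3), `n_timelines` (default 30, the
  evaluation-set scale the statistics are designed for).

The default four-profile study (`default_study_profiles`) mirrors the
qualitative diversity ordering the framework is meant to detect: a maximally
varied human profile, a moderately varied naive baseline, and two heavily
templated model profiles. The default ratings spec places per-system Likert
means in the reported ordering (humans highest on factual consistency and
overall usefulness, the naive baseline lowest elsewhere), SD 1.0; scores are
normal draws rounded to integers and clamped to 1–5, so realized means near
the scale ends shrink slightly toward the middle.

Determinism: one global seed drives an independent substream per
(system, component) keyed by a stable hash of the system id, so adding a
profile to a spec never changes the output of profiles already present, and
the same spec is byte-identical across runs and platforms.

What the generator does **not** emulate: real clinical language, discourse
coherence, the posts/timelines themselves, or LLM failure modes. Passing
tests on synthetic corpora therefore validate the *measurement machinery*
(metrics, tests, calibration, monotone response to known diversity dials),
not any claim about real summarizers.

## Report tables

`build_report` lays out metrics × systems with an `Average` row. Published
tables of this kind are ambiguous about whether their Average was computed
from the rounded cells shown or from full precision, and the two can differ
in the second decimal; both modes are provided (`from_rounded_cells`
reproduces printed-cell arithmetic, `from_unrounded` is the default for new
analyses) and the mode is embedded in the table metadata. Display rounding
is decimal half-up, not banker's.

## Problem sizes in the checks

The acceptance checks run at: 500 random token pairs (length ≤ 8, vocabulary
4) against the brute-force oracle; 20 statistic configurations at n = 6 for
Monte-Carlo-vs-exhaustive agreement (B = 4000); 500 null replicates at the
default 30-timeline scale with B = 1000 for type-I calibration; 20 seeds per
monotonicity dial. These sizes give binomial/oracle resolution well inside
the asserted bounds while keeping the whole suite quick on one CPU.

## Known limitations

* The reference embedder is lexical; it cannot detect paraphrase-level
  semantic similarity the way a transformer encoder would. The contract and
  registry exist precisely so a real encoder can be dropped in.
* Self-ROUGE conflates topical overlap with stylistic overlap; on corpora
  where all timelines genuinely share content, low self-ROUGE is not
  attainable even for a perfectly personalized system.
* The permutation test is exact only under within-timeline exchangeability;
  systems with different summary-length distributions are still validly
  tested (the statistic difference is what is permuted), but the test says
  nothing about *why* distributions differ.
* Exhaustive mode is limited to 20 timelines (2^20 assignments); beyond
  that, Monte-Carlo with B ≥ 1000 is the supported path.
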