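# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data results do and do not show.

## Corpus model

A corpus is a flat list of user↔bot exchanges with user id, country, local
wall-clock timestamp, and both texts. Region is a deterministic function of
country over the eight study countries (Eastern: Malaysia, the Philippines,
India, Indonesia, Thailand; Western: Canada, the United Kingdom, the United
States); any other country is a hard error rather than a silent default,
because a misassigned region would contaminate every downstream contrast.
Timestamps are treated as already local — no timezone arithmetic is
performed (the upstream platform assigns country from the device timezone,
so local time is what arrives).

Keyword filtering is raw case-insensitive substring matching, deliberately
untokenized: the stem "depress" must hit "depressed", "depression",
"depressing", and multiword phrases ("feeling low", "hate myself") must
match across token boundaries. The cost is occasional over-matching (e.g.
"sad" inside "Sadie"), which mirrors how such corpora are actually built.

PII masking replaces maximal runs of ≥ N consecutive digits (default N = 4;
shorter runs like ages are kept) with asterisks of equal length; the
operation is length-preserving and idempotent.

## Synthetic generator

The generator is the package's stand-in for a proprietary chat-log corpus;
its defaults encode the study conditions the analyses assume.

* **Users and volume.** `n_users_per_region` users per region (default
  2000); utterances per user are 1 + Poisson(mean − 1) (default mean 3),
  with an optional gamma-Poisson over-dispersion knob. One-per-user
  sampling downstream therefore has real work to do.
* **Category structure.** Each utterance carries a latent category from the
  8-way discourse scheme, drawn from a region-specific mixture. The default
  mixtures use the four per-region shares the published analysis prints
  (apathy/sadness 50.63% E / 48.49% W, dysfunctional thoughts 8.68/11.36,
  social struggles 7.15/9.10, seeking relief 8.24/6.82), the pooled-only
  values for hiding-behind-a-mask (3.95%) and etc (18.24%) applied to both
  regions, and the unprinted residual (≈2–3%) split between lifestyle
  challenges and suicidal thoughts. Text is assembled from small
  per-category template banks with distinctive content words, so the
  categories are learnable from bag-of-words — by design.
* **Diurnal model.** Hour-of-day is a mixture of a uniform background and a
  wrapped, discretized Gaussian evening peak: weight 0.6, SD 1.5 h, peak at
  21 h (Eastern) / 19 h (Western). The sharp SD makes the modal hour
  recoverable from ~10⁴ timestamps; a broader peak would need far larger
  corpora for the argmax to stabilize.
* **Keywords and style.** With probability `keyword_rate` (default 0.9) an
  utterance embeds a mood keyword if its template does not already contain
  one; at `keyword_rate = 1` keyword filtering retains the whole corpus.
  Region-styled signal phrases (Eastern: present-tense feeling language;
  Western: health/swear tokens; rate 0.35) make the lexicon contrasts
  recoverable with the planted sign. Filler-token noise (rate 0.3) roughens
  the text. These magnitudes are knobs, not claims about real chat logs.
* **Raters.** A fraction `labeled_fraction` (default 1%) of utterances is
  annotated by `n_raters` (default 4) simulated raters who emit the true
  category with probability `rater_accuracy`, else a uniform wrong one. The
  default accuracy 0.94 comes from a closed form chosen before any testing:
  pairwise agreement is a² + (1−a)²/7 and chance agreement follows from the
  mixture marginals, so a ≈ 0.94 puts Fleiss κ at ≈ 0.85, the agreement
  level the study reports. The same one-knob error model then keeps ≈ 98%
  of items under the 3-of-4 consensus rule, more than the study's ≈ 90%; a
  single accuracy parameter cannot match both numbers, and κ was
  prioritized because it is the statistic the agreement machinery is tested
  against. A two-parameter error model (per-item difficulty) could match
  both but is not needed by any consumer of the generator.
* **Determinism.** One seed per `generate()` call; independent sub-streams
  are derived by stable (blake2s) hashing of (seed, purpose), and the
  pipeline derives per-stage seeds the same way, so any stage can be re-run
  alone and reproduce its slice of the randomness. Derived seeds stay below
  2³¹.

What passing tests on this generator show: that the statistics, the
agreement machinery, the feature stack, the self-training loop and the
share/χ² comparisons are implemented correctly and recover planted
structure. What they do not show: anything about classifier performance on
real chat text, which is vastly noisier, multilingual, and not
template-separable.

## Statistics

* **Lexicon scores** follow the LIWC convention: percentage of tokens
  matching a category's patterns (literal whole-token, or `stem*` prefix),
  base = all tokens of the utterance. Zero-token utterances have no score
  and are excluded from group statistics (an explicit error at the
  single-utterance level, a silent skip at corpus level).
* **Welch t** is the closed form on summary statistics; sample SDs use
  denominator n − 1. Degrees of freedom use the Welch–Satterthwaite formula
  rewritten in variance fractions, df = 1/(f₁²/(n₁−1) + f₂²/(n₂−1)) with
  fᵢ = vᵢ/(v₁+v₂), which survives subnormal variances where the textbook
  form hits 0/0. Both-SDs-zero is a degenerate-input error. p-values are
  kept at full precision; journal-style rounding happens only in report
  rendering.
* **Fleiss κ** delegates to statsmodels with one guard: when every
  assignment in the matrix is the same single category, chance agreement is
  1 and κ is returned as 1 with a `degenerate` flag instead of 0/0.
  Per-category values are specific agreement: the probability that a second
  rater matches a first rater's choice of that category.
* **Consensus filter** keeps an item iff its modal label has multiplicity ≥
  `min_agree` (default 3 of 4); modal ties at or above the threshold
  (possible only in non-default geometries) are discarded.
* **n-grams** never cross utterance boundaries; single-character tokens and
  pure punctuation are always removed, stopwords optionally (packaged,
  versioned list — the published top-unigram tables visibly retain
  stopwords, so the flag matters). Ties break by count then lexicographic.
* **χ² comparisons** are per-category 2×2 Pearson tests (in-category vs
  not × group A vs B), df = 1, no continuity correction (large-sample
  setting; a flag could add it), plus one overall 2×8 test. An expected
  cell < 1 flags the row unreliable. Percentages are rounded half-up to
  2 dp only for display; all tests run on exact counts.

## Features and classifiers

The vocabulary keeps tokens with corpus frequency ≥ 5, sorted
lexicographically for index stability. Default vocabulary scope is the
training split only (leakage control); `vocab_scope="all"` reproduces the
whole-dataset convention some studies use. BoW is presence (multi-hot), not
counts. PoS counts use a frozen 46-tag Penn-Treebank-style inventory; the
default backend is a rule-based tagger (closed-class lexicon, digit and
punctuation detection, suffix heuristics, NN fallback) that can only emit
inventory tags, and tests use a lookup-table tagger as an exact oracle. The
default sentence embedder hashes character 3–5-grams into `dim` signed
buckets (default 768) and L2-normalizes — deterministic and download-free;
a pretrained-transformer backend can stand behind the same contract but
errors loudly rather than falling back silently when unavailable.

All five classifier families run with fixed, seeded default
hyperparameters (SVC rbf C=1; random forest 200 trees; Gaussian NB;
XGBoost 100×depth-4; MLP one hidden layer of 100, max 300 iterations).
Labels are re-encoded to consecutive integers at fit time so partial-class
training sets fit everywhere, and probability rows are re-expanded to all 8
categories (absent classes get probability 0).

Self-training is the literal 4-step loop: train, pseudo-label pool items
with max probability **strictly above** the threshold (default 0.9), freeze
those labels and retrain from scratch, repeat until no new labels, an empty
pool, or `max_iters`. High-confidence evaluation uses **≥** the threshold —
the two inequalities intentionally differ, matching how selection and
reporting are usually phrased — and an empty retained set returns an
explicit empty signal, never NaN metrics. Macro AUROC is one-vs-rest over
classes with both positives and negatives in the evaluation set; the rest
are skipped and reported.

## Benchmark and problem sizes

The self-training benchmark generates 25,000 utterances with a uniform
8-category mixture, annotates 1% via the simulated panel, consensus-filters,
splits 80/20, and compares the pseudo-labeling MLP (threshold 0.9, 2
iterations, 64-dim embedding) with its supervised baseline on the same
split. Uniform mixture: with Figure-style skewed mixtures a 1% labeled
subset regularly misses the rare classes entirely, making the comparison
undefined; the benchmark's claim is about the training procedure, not the
class prior. Size 25,000: 1% → ~250 labeled → ~50 test items, the smallest
test set on which 8-class macro-F1 is stable enough to compare two models
to within 0.02 (at ~16 test items the statistic is dominated by single-item
noise). The pipeline's default `RunConfig` is a deliberately tiny smoke
configuration (~1,200 utterances, 5% labeled, all stages in a few seconds);
statistical defaults live in `GeneratorConfig`.

## Known limitations

* Template text is a caricature: real utterances are code-switched, typo-
  ridden and topically entangled; no metric here transfers.
* The demonstration lexicons are a few patterns per category — enough to
  test the engine, not to do psycholinguistics.
* The rule-based tagger is heuristic; its counts are stable and
  inventory-valid but not linguistically accurate. Swap in a statistical
  tagger via the backend contract for real analyses.
* The one-knob rater model cannot simultaneously match a target κ and a
  target consensus-retention rate (see above).
* Only English; only hour-resolution temporal structure; bot responses are
  canned strings.
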