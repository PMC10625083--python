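# chatmood

Analysis pipeline for **depressive-mood discourse in open-domain chatbot
logs**, for computational social scientists and digital mental-health
researchers who want to study how people talk to a small-talk bot about
sadness and depression — and how that differs between Eastern and Western
user populations and across platforms.

Chat platforms rarely release raw logs, so the package pairs every analysis
stage with a synthetic chat-log generator whose latent structure (category
mixtures, diurnal peaks, rater behaviour) is known, making the whole
pipeline testable end to end without any data download.

## What it computes

**Corpus construction** (`chatlog_io`). Keyword filtering with the two mood
keyword sets (9 depressed/sad phrases such as *depress*, *feeling low*,
*hate myself*; 14 happy/excited phrases), matched as case-insensitive
substrings so stems hit inflections; deterministic country → region mapping
(Eastern = MY, PH, IN, ID, TH; Western = CA, GB, US); one-utterance-per-user
sampling; PII masking of digit runs.

**Descriptive analytics** (`lexicon_stats`). LIWC-style word-category
percentages — an utterance's score for category *c* is
100 · (#tokens matching *c*'s patterns)/(#tokens) — compared between
regions with Welch's unequal-variance t-test,

t = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂),

with Welch–Satterthwaite degrees of freedom; top-*k* uni/bigram tables; and
relative hourly chat frequency (per-hour count / region total). The
proprietary LIWC dictionaries are not shipped; a small demonstration
dictionary set in the same one-pattern-per-line format is, and users can
supply their own.

**Annotation** (`annotation`). Eight discourse categories (dysfunctional
thoughts, lifestyle challenges, social struggles, hiding behind a mask,
apathy/sadness, suicidal thoughts, seeking relief, etc). Fleiss κ for a
fixed rater panel, κ = (P̄ − P̄ₑ)/(1 − P̄ₑ), and consensus filtering that
keeps an item iff ≥ 3 of 4 raters agree.

**Features and classification** (`features`, `ssl_classify`). Multi-hot
bag-of-words over a min-count-5 vocabulary ‖ 46-dim PoS tag counts ‖ a
768-dim sentence embedding (offline hashing backend by default) — in the
reference configuration 6027 + 46 + 768 = 6841 dims. Five classifier
families (SVM, random forest, naive Bayes, gradient-boosted trees, MLP) and
the classic pseudo-labeling loop: train on the ~1% labeled subset, absorb
unlabeled items whose max class probability exceeds 0.9, retrain from
scratch, repeat; evaluation optionally restricted to high-confidence
(≥ 0.9) test items.

**Distribution comparison** (`distribution_compare`). Per-group category
shares (half-up 2-dp percentages over exact counts), per-category 2×2
Pearson χ² between regions, and comparison against a packaged Twitter
reference distribution containing only printed shares with per-cell
provenance.

## Worked example

```python
from chatmood.synthetic_corpus import GeneratorConfig, generate
from chatmood.annotation import fleiss_kappa, consensus_filter
from chatmood.lexicon_stats import hourly_profile

corpus = generate(GeneratorConfig(n_users_per_region=2500,
                                  utterances_per_user_mean=2.0,
                                  labeled_fraction=0.15, seed=29))
profiles = hourly_profile(corpus.records)
print({r: p.peak_hour for r, p in profiles.items()})
print(round(fleiss_kappa(corpus.annotations).kappa, 2))
kept = consensus_filter(corpus.annotations).kept
print(len(kept), "/", len(corpus.annotations.items))
```

prints

```
{'Eastern': 21, 'Western': 19}
0.84
1465 / 1491
```

i.e. the generator's evening chat peaks (9–10 PM Eastern, 7–8 PM Western)
are recovered from the timestamps, the simulated 4-rater panel lands at
κ ≈ 0.85 (high agreement), and ~98% of annotated items survive the
3-of-4 consensus filter.

The same run from a shell:

```bash
chatmood run --seed 12 --out-dir out     # writes out/report.md + report.json
chatmood simulate --seed 2 --out-dir sim # corpus.jsonl, labels.tsv, annotations.tsv
```

Every artifact records the seed and a hash of the full configuration.

## Limitations

Synthetic corpora are template-based, far more separable than real chat
text; classifier metrics on them bound nothing about real data (see
`docs/methods.md`). The shipped lexicons are demonstrations, not the
licensed LIWC dictionaries. Only English text is modeled.
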