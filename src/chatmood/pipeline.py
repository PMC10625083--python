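"""End-to-end orchestration: simulate → filter/sample → descriptive stats →
agreement → features → (self-)training → distributions → report.

:class:`RunConfig` mirrors every stage's knobs, rejects unknown keys, and
hashes canonically so every artifact can name the exact configuration and
seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import annotation, chatlog_io, distribution_compare, features
from . import lexicon_stats, ssl_classify
from .annotation import CATEGORIES, CATEGORY_INDEX
from .synthetic_corpus import GeneratorConfig, generate

STAGES = ("simulate", "filter", "sample", "lexstats", "ngrams", "temporal",
          "agreement", "featurize", "train", "selftrain", "distributions",
          "report")


@dataclass
class RunConfig:
    """Whole-pipeline configuration.  Defaults are a small smoke-scale run
    (about a thousand utterances) that exercises every stage quickly;
    corpus-level statistical defaults live in :class:`GeneratorConfig`."""

    seed: int = 0
    out_dir: str = "chatmood_out"
    log_level: str = "INFO"
    # generator overrides (study-scale statistical defaults come from
    # GeneratorConfig; the smoke run shrinks the corpus and enlarges the
    # labeled fraction so every class reaches the classifier stages)
    n_users_per_region: int = 300
    utterances_per_user_mean: float = 2.0
    labeled_fraction: float = 0.05
    rater_accuracy: float | None = None
    keyword_set: str = "depressed_sad"
    # study-1 knobs
    ngram_k: int = 10
    remove_stopwords: bool = True
    # annotation
    min_agree: int = 3
    # features
    vocab_min_count: int = 5
    vocab_scope: str = "train"  # train | all
    embedding_dim: int = 64
    # classification
    model_families: tuple[str, ...] = ("mlp",)
    test_fraction: float = 0.2
    stratified_split: bool = False
    selftrain_threshold: float = 0.9
    highconf_threshold: float = 0.9
    max_iters: int = 3
    mlp_hidden: int = 64

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.vocab_scope not in ("train", "all"):
            raise ValueError("vocab_scope must be 'train' or 'all'")
        for fam in cfg.model_families:
            if fam not in ssl_classify.MODEL_FAMILIES:
                raise ValueError(f"unknown model family {fam!r}")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def generator_config(self) -> GeneratorConfig:
        gc = GeneratorConfig(
            n_users_per_region=self.n_users_per_region,
            utterances_per_user_mean=self.utterances_per_user_mean,
            labeled_fraction=self.labeled_fraction,
            keyword_set_name=self.keyword_set,
            seed=stage_seed(self.seed, "simulate"),
        )
        if self.rater_accuracy is not None:
            gc.rater_accuracy = self.rater_accuracy
        return gc


def stage_seed(seed: int, stage: str) -> int:
    """Global seed → per-stage sub-seed by stable hashing (stage reruns are
    reproducible in isolation)."""
    digest = hashlib.blake2s(f"{seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order; returns a results
    dict and writes artifacts under ``config.out_dir``."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    corpus = generate(config.generator_config())
    records = corpus.records
    if "simulate" in stages:
        chatlog_io.write_corpus(records, out / "corpus.jsonl")
        corpus.annotations.to_frame().to_csv(out / "annotations.tsv", sep="\t",
                                             index=False)
        with (out / "labels.tsv").open("w", encoding="utf-8") as fh:
            fh.write("utterance_id\tcategory\n")
            for utt, cat in corpus.true_labels.items():
                fh.write(f"{utt}\t{cat}\n")
        results["simulate"] = {"n_records": len(records),
                               "n_annotated": len(corpus.annotations.items)}
        if stages == ("simulate",):
            return results

    keys = chatlog_io.load_keyword_set(config.keyword_set)
    filtered = chatlog_io.filter_by_keywords(records, keys) if "filter" in stages else records
    if "filter" in stages:
        results["filter"] = {"kept": len(filtered), "of": len(records)}
    sampled = (chatlog_io.sample_one_per_user(filtered, stage_seed(config.seed, "sample"))
               if "sample" in stages else filtered)
    if "sample" in stages:
        results["sample"] = {"kept": len(sampled)}

    east_texts = [r.user_text for r in sampled if r.region == "Eastern"]
    west_texts = [r.user_text for r in sampled if r.region == "Western"]

    if "lexstats" in stages:
        lex_rows = []
        for name, lex in lexicon_stats.load_demo_lexicons().items():
            a = lexicon_stats.score_corpus(east_texts, lex)
            b = lexicon_stats.score_corpus(west_texts, lex)
            if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
                continue
            w = lexicon_stats.welch_t_from_samples(a, b)
            lex_rows.append({"category": name, "t": w.t, "df": w.df, "p": w.p,
                             "mean_east": w.mean1, "sd_east": w.sd1,
                             "mean_west": w.mean2, "sd_west": w.sd2})
        results["lexstats"] = lex_rows

    if "ngrams" in stages:
        results["ngrams"] = {
            region: {
                f"{kind}grams": [
                    {"ngram": " ".join(g), "proportion": p}
                    for g, p in lexicon_stats.top_ngrams(
                        texts, n=n, k=config.ngram_k,
                        remove_stopwords=config.remove_stopwords).entries
                ]
                for kind, n in (("uni", 1), ("bi", 2))
            }
            for region, texts in (("Eastern", east_texts), ("Western", west_texts))
        }

    if "temporal" in stages:
        profiles = lexicon_stats.hourly_profile(sampled)
        results["temporal"] = {
            region: {"peak_hour": prof.peak_hour, "freq": prof.freq.tolist()}
            for region, prof in profiles.items()
        }

    consensus = annotation.consensus_filter(corpus.annotations,
                                            min_agree=config.min_agree)
    if "agreement" in stages:
        agr = annotation.fleiss_kappa(corpus.annotations)
        results["agreement"] = {
            "fleiss_kappa": agr.kappa,
            "kept": len(consensus.kept),
            "discarded": len(consensus.discarded),
            "per_category_agreement": agr.per_category_agreement,
        }

    model = None
    needs_features = {"featurize", "train", "selftrain", "distributions"} & set(stages)
    if needs_features:
        text_of = {r.utterance_id: r.user_text for r in records}
        labeled_ids = [u for u in consensus.kept if u in text_of]
        y_labeled = np.array([CATEGORY_INDEX[consensus.kept[u]] for u in labeled_ids])
        pool_ids = [r.utterance_id for r in records
                    if r.utterance_id not in consensus.kept]
        split_sd = stage_seed(config.seed, "split")
        tr_idx, te_idx = ssl_classify.split_train_test(
            np.zeros((len(labeled_ids), 1)), y_labeled,
            test_fraction=config.test_fraction, seed=split_sd,
            stratified=config.stratified_split)
        train_texts = [text_of[labeled_ids[i]] for i in tr_idx]
        vocab_texts = (train_texts if config.vocab_scope == "train"
                       else [r.user_text for r in records])
        vocab = features.build_vocab(vocab_texts, min_count=config.vocab_min_count)
        embedder = features.HashingEmbedder(dim=config.embedding_dim)
        X_labeled = features.featurize_corpus([text_of[u] for u in labeled_ids],
                                              vocab, embedder=embedder)
        X_pool = features.featurize_corpus([text_of[u] for u in pool_ids],
                                           vocab, embedder=embedder)
        results["featurize"] = {"vocab_size": len(vocab),
                                "pos_dim": len(features.TAG_INVENTORY),
                                "embedding_dim": embedder.dim,
                                "total_dim": X_labeled.shape[1]}
        X_tr, y_tr = X_labeled[tr_idx], y_labeled[tr_idx]
        X_te, y_te = X_labeled[te_idx], y_labeled[te_idx]
        mlp_spec = ssl_classify.ModelSpec(
            "mlp", {"hidden_layer_sizes": (config.mlp_hidden,), "max_iter": 300},
            seed=stage_seed(config.seed, "model"))

        if "train" in stages:
            specs = [mlp_spec if fam == "mlp"
                     else ssl_classify.ModelSpec(fam, seed=stage_seed(config.seed, "model"))
                     for fam in config.model_families]
            rows = ssl_classify.train_and_evaluate(specs, X_tr, y_tr, X_te, y_te)
            results["train"] = [
                {"family": spec.family,
                 "metrics": None if m is None else dataclasses.asdict(m),
                 "error": err}
                for spec, m, err in rows
            ]

        if {"selftrain", "distributions"} & set(stages):
            model, history = ssl_classify.self_train(
                mlp_spec, X_tr, y_tr, X_pool,
                threshold=config.selftrain_threshold, max_iters=config.max_iters)
            full = ssl_classify.evaluate(y_te, model.predict_proba(X_te))
            high = ssl_classify.high_confidence_eval(
                model, X_te, y_te, threshold=config.highconf_threshold)
            results["selftrain"] = {
                "iterations": len(history),
                "stop_reason": history[-1].stop_reason if history else "no_new_labels",
                "n_pseudo_labeled": sum(len(h.pseudo_labeled) for h in history),
                "metrics_full": dataclasses.asdict(full),
                "metrics_high_confidence": None if high is None else dataclasses.asdict(high),
            }

    if "distributions" in stages and model is not None:
        region_of = {r.utterance_id: r.region for r in records}
        proba = model.predict_proba(X_pool)
        conf = proba.max(axis=1)
        keep = conf >= config.highconf_threshold
        pred_labels = {
            u: CATEGORIES[int(c)]
            for u, c, k in zip(pool_ids, np.argmax(proba, axis=1), keep) if k
        }
        pred_labels.update({u: consensus.kept[u] for u in labeled_ids})
        groups = {u: region_of[u] for u in pred_labels}
        dists = distribution_compare.category_shares(pred_labels, groups)
        section: dict = {g: {"total": d.total, "percent": d.percent}
                         for g, d in dists.items()}
        if "Eastern" in dists and "Western" in dists:
            section["chi_square_per_category"] = [
                dataclasses.asdict(r) for r in
                distribution_compare.per_category_chi_square(
                    dists["Eastern"], dists["Western"])
            ]
            pooled = distribution_compare.CategoryDistribution(
                group="all",
                counts={c: dists["Eastern"].counts.get(c, 0)
                        + dists["Western"].counts.get(c, 0) for c in CATEGORIES})
            section["twitter_comparison"] = distribution_compare.compare_to_reference(
                pooled, distribution_compare.load_twitter_reference())
        results["distributions"] = section

    if "report" in stages:
        md, machine = distribution_compare.render_report(
            {k: v for k, v in results.items() if k not in ("config_hash", "seed")},
            seed=config.seed, config_hash=config.config_hash())
        (out / "report.md").write_text(md, encoding="utf-8")
        (out / "report.json").write_text(
            json.dumps(machine, indent=2, sort_keys=True, default=str),
            encoding="utf-8")
        results["report"] = {"markdown": str(out / "report.md"),
                             "json": str(out / "report.json")}
    return results


def benchmark_self_training(seed: int, n_users_per_region: int = 12500,
                            labeled_fraction: float = 0.01,
                            threshold: float = 0.9, max_iters: int = 2,
                            embedding_dim: int = 64) -> dict:
    """The synthetic self-training benchmark: ~1% labeled, 8 balanced
    categories, separable templates plus token noise.

    Trains the supervised MLP baseline and the pseudo-labeling MLP on the
    same split and reports macro-F1 for both, plus full-test vs
    high-confidence-subset accuracy for the self-trained model.
    """
    uniform = {c: 1.0 / len(CATEGORIES) for c in CATEGORIES}
    gc = GeneratorConfig(
        n_users_per_region=n_users_per_region,
        utterances_per_user_mean=1.0,
        category_mixture={"Eastern": dict(uniform), "Western": dict(uniform)},
        labeled_fraction=labeled_fraction,
        seed=stage_seed(seed, "benchmark"),
    )
    corpus = generate(gc)
    text_of = {r.utterance_id: r.user_text for r in corpus.records}
    consensus = annotation.consensus_filter(corpus.annotations)
    labeled_ids = list(consensus.kept)
    y = np.array([CATEGORY_INDEX[consensus.kept[u]] for u in labeled_ids])
    pool_ids = [r.utterance_id for r in corpus.records
                if r.utterance_id not in consensus.kept]

    tr, te = ssl_classify.split_train_test(np.zeros((len(y), 1)), y,
                                           seed=stage_seed(seed, "split"),
                                           stratified=False)
    vocab = features.build_vocab([text_of[labeled_ids[i]] for i in tr], min_count=5)
    embedder = features.HashingEmbedder(dim=embedding_dim)
    X = features.featurize_corpus([text_of[u] for u in labeled_ids], vocab,
                                  embedder=embedder)
    X_pool = features.featurize_corpus([text_of[u] for u in pool_ids], vocab,
                                       embedder=embedder)
    spec = ssl_classify.ModelSpec("mlp", {"hidden_layer_sizes": (64,),
                                          "max_iter": 300},
                                  seed=stage_seed(seed, "model"))
    baseline = ssl_classify.fit_model(spec, X[tr], y[tr])
    base_m = ssl_classify.evaluate(y[te], baseline.predict_proba(X[te]))
    model, history = ssl_classify.self_train(spec, X[tr], y[tr], X_pool,
                                             threshold=threshold,
                                             max_iters=max_iters)
    self_m = ssl_classify.evaluate(y[te], model.predict_proba(X[te]))
    high = ssl_classify.high_confidence_eval(model, X[te], y[te], threshold=0.9)

    truth_idx = {u: CATEGORY_INDEX[corpus.true_labels[u]] for u in pool_ids}
    pseudo = {i: lab for h in history for i, (lab, _) in h.pseudo_labeled.items()}
    pseudo_acc = (float(np.mean([truth_idx[pool_ids[i]] == lab
                                 for i, lab in pseudo.items()]))
                  if pseudo else float("nan"))
    return {
        "n_records": len(corpus.records),
        "n_labeled": len(labeled_ids),
        "baseline_macro_f1": base_m.f1,
        "selftrain_macro_f1": self_m.f1,
        "full_accuracy": self_m.accuracy,
        "highconf_accuracy": None if high is None else high.accuracy,
        "highconf_n": 0 if high is None else high.n_eval,
        "n_pseudo_labeled": len(pseudo),
        "pseudo_label_accuracy": pseudo_acc,
        "iterations": len(history),
    }
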