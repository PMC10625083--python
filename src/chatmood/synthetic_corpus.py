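"""Synthetic chat-log generator with the statistical structure the analysis assumes.

Emulates a keyword-selected depressive-discourse corpus from an open-domain
chatbot: per-region (Eastern/Western) users, a latent 8-category discourse
structure with region-specific mixture weights, diurnal timestamps with an
evening peak (later for Eastern users), embedded mood keywords, and a small
labeled subset annotated by a panel of simulated raters of controllable
accuracy.  Text is assembled from per-category template banks plus filler
tokens — deliberately simple, separable English, not natural language.

Everything is deterministic for a fixed seed; independent sub-streams are
derived per purpose by stable hashing so stages can be regenerated alone.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .annotation import CATEGORIES, AnnotationMatrix
from .chatlog_io import ChatRecord, load_keyword_set

EASTERN_COUNTRIES = ("Malaysia", "Philippines", "India", "Indonesia", "Thailand")
WESTERN_COUNTRIES = ("Canada", "United Kingdom", "United States")

# Region-specific category mixtures. The four per-region shares that the
# study prints (apathy/sadness, dysfunctional thoughts, social struggles,
# seeking relief) are used directly; hiding-behind-a-mask and etc are only
# printed pooled and are applied to both regions; the unprinted residual is
# split between lifestyle challenges and suicidal thoughts.
EASTERN_MIXTURE: dict[str, float] = {
    "dysfunctional_thoughts": 0.0868,
    "lifestyle_challenges": 0.0161,
    "social_struggles": 0.0715,
    "hiding_behind_mask": 0.0395,
    "apathy_sadness": 0.5063,
    "suicidal_thoughts": 0.0150,
    "seeking_relief": 0.0824,
    "etc": 0.1824,
}
WESTERN_MIXTURE: dict[str, float] = {
    "dysfunctional_thoughts": 0.1136,
    "lifestyle_challenges": 0.0106,
    "social_struggles": 0.0910,
    "hiding_behind_mask": 0.0395,
    "apathy_sadness": 0.4849,
    "suicidal_thoughts": 0.0098,
    "seeking_relief": 0.0682,
    "etc": 0.1824,
}

_TEMPLATES: dict[str, tuple[str, ...]] = {
    "dysfunctional_thoughts": (
        "i hate everything i hate life i hate myself",
        "i am worthless and hopeless about everything",
        "everything i do is a failure i am useless",
        "i am a burden and nothing about me is good",
    ),
    "lifestyle_challenges": (
        "i cant sleep at night because i am so stressed",
        "i have no appetite and cant eat anything today",
        "i am exhausted and cant do my chores anymore",
        "my sleep is broken and daily tasks feel impossible",
    ),
    "social_struggles": (
        "nobody understands me and i am so lonely",
        "my friends left me out again and it hurts",
        "i told her about my depression and she called me crazy",
        "i have no one to talk to about this loneliness",
    ),
    "hiding_behind_mask": (
        "i pretend to be okay but i am not okay",
        "i smile outside but inside i am falling apart",
        "yeah just a bit depressed i will be okay",
        "i act fine at school so nobody notices anything",
    ),
    "apathy_sadness": (
        "i am sad and crying now",
        "i feel so empty and sad about nothing",
        "im so sad and numb i just want to cry",
        "everything feels grey and i am sad again",
    ),
    "suicidal_thoughts": (
        "i want to die but i dont kill myself because of pain",
        "i keep thinking about ending my life",
        "sometimes i want to hurt myself and disappear",
        "i wish i was dead and gone forever",
    ),
    "seeking_relief": (
        "can you give me advice to heal my sad",
        "i have depression and anxiety what should i do",
        "please help me cope with these depressive moods",
        "how do i get better tell me something helpful",
    ),
    "etc": (
        "why are you sad little bot",
        "dont be sad i am here for you",
        "that is sad to hear my friend",
        "sighs sadly and walks away sadly",
    ),
}

_HAPPY_TEMPLATES: tuple[str, ...] = (
    "i am so happy and excited today",
    "this is amazing i feel wonderful",
    "i am proud of myself and overjoyed",
    "what a blessed and excellent day i enjoy it",
)

_EASTERN_FLAVOR = (
    "i feel pain right now",
    "my heart hurt so much right now",
    "these feelings are heavy right now",
    "i feel sore inside now",
)
_WESTERN_FLAVOR = (
    "this damn headache is back",
    "my health is a mess lately",
    "hell my body aches and my doctor is useless",
    "i was at the hospital last week",
)

_FILLERS = ("haha", "hmm", "really", "please", "today", "well", "ok", "like", "uh")

_BOT_REPLIES = (
    "i am here for you",
    "tell me more about that",
    "that sounds hard",
    "do you want to talk about it",
    "",
)

_EPOCH_START = datetime(2016, 5, 1)
_EPOCH_DAYS = (datetime(2020, 12, 31) - _EPOCH_START).days


@dataclass(frozen=True)
class DiurnalConfig:
    """Hour-of-day model: mixture of a uniform background and a wrapped,
    discretized Gaussian evening peak.

    weight    — mixture weight of the peaked component, in [0, 1]
    peak_hour — mode of the peaked component, in [0, 23]
    spread    — Gaussian SD in hours
    """

    weight: float = 0.6
    peak_hour: int = 21
    spread: float = 1.5

    def hour_pmf(self) -> np.ndarray:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("diurnal weight must be in [0, 1]")
        if not 0 <= self.peak_hour <= 23:
            raise ValueError("peak_hour must be in [0, 23]")
        hours = np.arange(24)
        d = np.minimum(np.abs(hours - self.peak_hour), 24 - np.abs(hours - self.peak_hour))
        peak = np.exp(-0.5 * (d / max(self.spread, 1e-9)) ** 2)
        peak /= peak.sum()
        return self.weight * peak + (1.0 - self.weight) / 24.0


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults mirror the study conditions
    at desk scale (region mixtures, evening peaks at 21h Eastern / 19h
    Western, ~1% labeled subset, 4 raters)."""

    n_users_per_region: int = 2000
    utterances_per_user_mean: float = 3.0
    utterances_per_user_dispersion: float = 1.0  # 1 → Poisson; >1 → gamma-Poisson
    category_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"Eastern": dict(EASTERN_MIXTURE),
                                 "Western": dict(WESTERN_MIXTURE)})
    diurnal: dict[str, DiurnalConfig] = field(
        default_factory=lambda: {"Eastern": DiurnalConfig(0.6, 21, 1.5),
                                 "Western": DiurnalConfig(0.6, 19, 1.5)})
    keyword_rate: float = 0.9
    region_style_rate: float = 0.35
    token_noise_rate: float = 0.3
    labeled_fraction: float = 0.01
    rater_accuracy: float = 0.94
    n_raters: int = 4
    keyword_set_name: str = "depressed_sad"
    seed: int = 0

    def validate(self) -> None:
        for region, mix in self.category_mixture.items():
            if set(mix) != set(CATEGORIES):
                raise ValueError(f"{region} mixture must cover exactly the 8 categories")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{region} mixture sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError("mixture weights must be non-negative")
        for p, name in ((self.keyword_rate, "keyword_rate"),
                        (self.region_style_rate, "region_style_rate"),
                        (self.token_noise_rate, "token_noise_rate"),
                        (self.labeled_fraction, "labeled_fraction"),
                        (self.rater_accuracy, "rater_accuracy")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for cfg in self.diurnal.values():
            cfg.hour_pmf()  # raises on invalid weight/peak
        if self.n_users_per_region < 1 or self.n_raters < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticCorpus:
    records: list[ChatRecord]
    true_labels: dict[str, str]
    annotations: AnnotationMatrix


def _substream(seed: int, purpose: str) -> np.random.Generator:
    """Independent RNG stream derived by stable hashing of (seed, purpose)."""
    digest = hashlib.blake2s(f"{seed}:{purpose}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") & 0x7FFFFFFF)


def _n_utterances(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Count ≥ 1: shifted Poisson, or gamma-Poisson when over-dispersed."""
    lam = max(mean - 1.0, 0.0)
    if dispersion > 1.0 and lam > 0:
        lam = rng.gamma(shape=lam / (dispersion - 1.0), scale=dispersion - 1.0)
    return 1 + int(rng.poisson(lam))


def _compose_text(rng: np.random.Generator, category: str, region: str,
                  config: GeneratorConfig, keyword_phrases: tuple[str, ...]) -> str:
    if config.keyword_set_name == "happy_excited":
        bank = _HAPPY_TEMPLATES
    else:
        bank = _TEMPLATES[category]
    parts = [bank[int(rng.integers(len(bank)))]]
    if rng.random() < config.region_style_rate:
        flavor = _EASTERN_FLAVOR if region == "Eastern" else _WESTERN_FLAVOR
        parts.append(flavor[int(rng.integers(len(flavor)))])
    text = " ".join(parts)
    if rng.random() < config.keyword_rate and not any(p in text for p in keyword_phrases):
        text += " " + keyword_phrases[int(rng.integers(len(keyword_phrases)))]
    if rng.random() < config.token_noise_rate:
        tokens = text.split()
        for _ in range(int(rng.integers(1, 3))):
            pos = int(rng.integers(len(tokens) + 1))
            tokens.insert(pos, _FILLERS[int(rng.integers(len(_FILLERS)))])
        text = " ".join(tokens)
    return text


def generate(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus, its latent true labels, and simulated annotations.

    Deterministic for a fixed ``config.seed``.  Raises on an invalid config
    before any generation.
    """
    config.validate()
    corpus_rng = _substream(config.seed, "corpus")

    records: list[ChatRecord] = []
    true_labels: dict[str, str] = {}
    cat_names = list(CATEGORIES)
    keyword_phrases = load_keyword_set(config.keyword_set_name).phrases
    uid = 0
    for region, countries, prefix in (("Eastern", EASTERN_COUNTRIES, "E"),
                                      ("Western", WESTERN_COUNTRIES, "W")):
        mix = config.category_mixture[region]
        probs = np.array([mix[c] for c in cat_names])
        hour_pmf = config.diurnal[region].hour_pmf()
        for u in range(config.n_users_per_region):
            user_id = f"{prefix}{u:06d}"
            country = countries[int(corpus_rng.integers(len(countries)))]
            k = _n_utterances(corpus_rng, config.utterances_per_user_mean,
                              config.utterances_per_user_dispersion)
            for _ in range(k):
                uid += 1
                utterance_id = f"u{uid:07d}"
                category = cat_names[int(corpus_rng.choice(len(cat_names), p=probs))]
                hour = int(corpus_rng.choice(24, p=hour_pmf))
                ts = (_EPOCH_START
                      + timedelta(days=int(corpus_rng.integers(_EPOCH_DAYS + 1)),
                                  hours=hour,
                                  minutes=int(corpus_rng.integers(60))))
                text = _compose_text(corpus_rng, category, region, config,
                                     keyword_phrases)
                records.append(ChatRecord(
                    utterance_id=utterance_id, user_id=user_id, country=country,
                    region=region, timestamp=ts, user_text=text,
                    bot_text=_BOT_REPLIES[int(corpus_rng.integers(len(_BOT_REPLIES)))],
                ))
                true_labels[utterance_id] = category

    n_labeled = math.ceil(config.labeled_fraction * len(records))
    label_rng = _substream(config.seed, "labeled-subset")
    labeled_idx = label_rng.choice(len(records), size=n_labeled, replace=False)
    labeled_items = [records[i].utterance_id for i in sorted(labeled_idx)]
    annotations = simulate_raters(
        {item: true_labels[item] for item in labeled_items},
        n_raters=config.n_raters, rater_accuracy=config.rater_accuracy,
        seed=config.seed)
    return SyntheticCorpus(records=records, true_labels=true_labels,
                           annotations=annotations)


def simulate_raters(true_labels: dict[str, str], n_raters: int,
                    rater_accuracy: float, seed: int) -> AnnotationMatrix:
    """Independent raters: each emits the true category with probability
    ``rater_accuracy``, otherwise a uniform draw from the other 7."""
    if not 0.0 <= rater_accuracy <= 1.0:
        raise ValueError("rater_accuracy must be a probability")
    rng = _substream(seed, "raters")
    items = list(true_labels)
    labels = np.empty((len(items), n_raters), dtype=object)
    for i, item in enumerate(items):
        truth = true_labels[item]
        others = [c for c in CATEGORIES if c != truth]
        for r in range(n_raters):
            if rng.random() < rater_accuracy:
                labels[i, r] = truth
            else:
                labels[i, r] = others[int(rng.integers(len(others)))]
    return AnnotationMatrix(items=items, labels=labels)
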