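"""Corpus analytics: dictionary word-category percentages, Welch t-tests,
top-k n-grams and relative hourly chat frequency.

The lexicon engine follows the LIWC convention: an utterance's score for a
category is the percentage of its tokens matching the category's patterns
(literal whole-token matches, or prefix stems written ``"xyz*"``).  The
proprietary LIWC dictionaries are not shipped; the package carries a small
demonstration dictionary set in the same plain-text format, and users may
point the engine at their own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .chatlog_io import ChatRecord

_STRIP = re.compile(r"^[^0-9a-z]+|[^0-9a-z']+$|^'+|'+$")


class UndefinedScoreError(ValueError):
    """Score requested for a zero-token text (excluded from group statistics)."""


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip non-alphanumerics at token edges
    (in-word apostrophes survive), drop empty tokens."""
    out = []
    for raw in text.lower().split():
        tok = raw
        while True:
            new = _STRIP.sub("", tok)
            if new == tok:
                break
            tok = new
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class CategoryLexicon:
    """Named pattern set: lowercase literals, or prefix stems ending in ``*``."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"lexicon {self.name!r} has no patterns")

    def matches(self, token: str) -> bool:
        for p in self.patterns:
            if p.endswith("*"):
                if token.startswith(p[:-1]):
                    return True
            elif token == p:
                return True
        return False


def load_lexicon(path: str | Path) -> CategoryLexicon:
    """Read a one-pattern-per-line lexicon file (``#`` starts a comment)."""
    path = Path(path)
    patterns = tuple(
        line.strip().lower() for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    return CategoryLexicon(name=path.stem, patterns=patterns)


def load_demo_lexicons() -> dict[str, CategoryLexicon]:
    """The packaged demonstration dictionary set (one file per category)."""
    root = resources.files("chatmood.data.lexicons")
    out = {}
    for ref in sorted(root.iterdir(), key=lambda r: r.name):
        if ref.name.endswith(".txt"):
            with resources.as_file(ref) as p:
                lex = load_lexicon(p)
            out[lex.name] = lex
    return out


def load_stopwords() -> frozenset[str]:
    ref = resources.files("chatmood.data").joinpath("stopwords_en.txt")
    return frozenset(
        line.strip() for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


def score_lexicon(text: str, lex: CategoryLexicon) -> float:
    """Percentage of tokens matching the lexicon, in [0, 100].

    Raises :class:`UndefinedScoreError` on zero-token text — such utterances
    carry no percentage and are excluded from group statistics.
    """
    tokens = tokenize(text)
    if not tokens:
        raise UndefinedScoreError("cannot score a zero-token text")
    hits = sum(1 for t in tokens if lex.matches(t))
    return 100.0 * hits / len(tokens)


def score_corpus(texts: Iterable[str], lex: CategoryLexicon) -> np.ndarray:
    """Defined scores only; zero-token texts are silently excluded."""
    out = []
    for text in texts:
        try:
            out.append(score_lexicon(text, lex))
        except UndefinedScoreError:
            continue
    return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch's two-sample t-test from summary statistics.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2); df by Welch–Satterthwaite;
    two-tailed p from Student's t.  SDs are sample SDs (denominator n−1).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("degenerate test: both standard deviations are zero")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    # Welch–Satterthwaite via variance fractions (stable when v_i underflow)
    f1, f2 = v1 / (v1 + v2), v2 / (v1 + v2)
    df = 1.0 / (f1 ** 2 / (n1 - 1) + f2 ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p),
                       mean1=mean1, sd1=sd1, n1=n1, mean2=mean2, sd2=sd2, n2=n2)


def welch_t_from_samples(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch t-test from raw scores (delegates to :func:`welch_t`)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 defined scores")
    return welch_t(float(a.mean()), float(a.std(ddof=1)), int(a.size),
                   float(b.mean()), float(b.std(ddof=1)), int(b.size))


@dataclass
class NgramTable:
    n: int
    entries: list[tuple[tuple[str, ...], float]]  # (token tuple, proportion)


def _ngram_tokens(text: str, stopwords: frozenset[str] | None) -> list[str]:
    # single-character tokens and pure-punctuation tokens always removed;
    # pure punctuation never survives tokenize(), so only length matters here
    toks = [t for t in tokenize(text) if len(t) > 1]
    if stopwords is not None:
        toks = [t for t in toks if t not in stopwords]
    return toks


def top_ngrams(texts: Iterable[str], n: int, k: int = 10,
               remove_stopwords: bool = True) -> NgramTable:
    """Top-k n-grams (n = 1 or 2) by proportion of all n-grams.

    N-grams never cross utterance boundaries.  Ties break lexicographically.
    Proportions are relative to the total n-gram count after filtering.
    """
    if n not in (1, 2):
        raise ValueError("only unigrams and bigrams are supported")
    if k < 1:
        raise ValueError("k must be >= 1")
    stop = load_stopwords() if remove_stopwords else None
    counts: dict[tuple[str, ...], int] = {}
    total = 0
    for text in texts:
        toks = _ngram_tokens(text, stop)
        for i in range(len(toks) - n + 1):
            gram = tuple(toks[i:i + n])
            counts[gram] = counts.get(gram, 0) + 1
            total += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return NgramTable(n=n, entries=[(g, c / total) for g, c in ranked])


@dataclass
class HourlyProfile:
    region: str
    freq: np.ndarray  # 24 relative frequencies summing to 1
    peak_hour: int


def hourly_profile(records: Iterable[ChatRecord]) -> dict[str, HourlyProfile]:
    """Relative hourly chat frequency per region: per-hour count divided by
    the region's total, with the argmax hour reported."""
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        counts.setdefault(rec.region, np.zeros(24, dtype=float))[rec.timestamp.hour] += 1
    out = {}
    for region, c in counts.items():
        freq = c / c.sum()
        out[region] = HourlyProfile(region=region, freq=freq,
                                    peak_hour=int(freq.argmax()))
    return out
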