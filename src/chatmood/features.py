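"""Feature stack for topic classification: multi-hot bag-of-words,
part-of-speech tag frequencies, a sentence embedding, and their concatenation.

The reference configuration concatenates a |vocab|-dim multi-hot BoW block,
a 46-dim PoS count block over a frozen Penn-Treebank-style tag inventory,
and a dense sentence embedding (768-dim by default), in that order.

Two backend families are pluggable:

* **taggers** — any object with ``tag(tokens) -> list[str]`` emitting only
  inventory tags.  The default is a lightweight rule-based English tagger
  (closed-class lexicon + suffix heuristics); a lookup-table tagger is
  provided for exact-oracle tests.
* **embedders** — any object with ``dim`` and ``embed(text) -> ndarray``.
  The default is an offline feature-hashing embedder over character n-grams,
  L2-normalized, fully deterministic and download-free.  A pretrained
  transformer can be slotted in behind the same contract where available;
  requesting one that is not installed raises immediately (never a silent
  fallback).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .lexicon_stats import tokenize


def load_tag_inventory() -> tuple[str, ...]:
    """The frozen 46-tag inventory, in vector-index order."""
    ref = resources.files("chatmood.data").joinpath("pos_tags.txt")
    # comment lines are "# ..." (hash + space); the bare "#" line IS a tag
    return tuple(
        line.strip() for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("# ")
    )


TAG_INVENTORY = load_tag_inventory()
_TAG_INDEX = {t: i for i, t in enumerate(TAG_INVENTORY)}


class UnknownTagError(ValueError):
    """A tagger emitted a tag outside the frozen inventory."""


# ---------------------------------------------------------------------------
# taggers

_CLOSED_CLASS = {
    "i": "PRP", "me": "PRP", "you": "PRP", "he": "PRP", "she": "PRP",
    "it": "PRP", "we": "PRP", "they": "PRP", "them": "PRP", "him": "PRP",
    "her": "PRP", "us": "PRP", "myself": "PRP", "yourself": "PRP",
    "my": "PRP$", "your": "PRP$", "his": "PRP$", "its": "PRP$",
    "our": "PRP$", "their": "PRP$",
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "no": "DT", "some": "DT", "any": "DT",
    "every": "DT", "each": "DT",
    "all": "PDT", "both": "PDT", "half": "PDT",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "yet": "CC",
    "in": "IN", "on": "IN", "at": "IN", "of": "IN", "for": "IN",
    "with": "IN", "about": "IN", "because": "IN", "if": "IN", "so": "IN",
    "from": "IN", "into": "IN", "after": "IN", "before": "IN", "by": "IN",
    "to": "TO",
    "can": "MD", "could": "MD", "will": "MD", "would": "MD", "shall": "MD",
    "should": "MD", "may": "MD", "might": "MD", "must": "MD", "cant": "MD",
    "am": "VBP", "are": "VBP", "is": "VBZ", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
    "do": "VBP", "does": "VBZ", "did": "VBD", "have": "VBP", "has": "VBZ",
    "had": "VBD",
    "not": "RB", "never": "RB", "always": "RB", "very": "RB", "too": "RB",
    "now": "RB", "again": "RB", "here": "RB", "there": "EX", "just": "RB",
    "more": "RBR", "most": "RBS",
    "up": "RP", "out": "RP", "off": "RP", "down": "RP",
    "who": "WP", "whom": "WP", "whose": "WP$", "which": "WDT",
    "when": "WRB", "where": "WRB", "why": "WRB", "how": "WRB",
    "what": "WP",
    "oh": "UH", "wow": "UH", "hey": "UH", "please": "UH", "yeah": "UH",
    "haha": "UH", "hmm": "UH", "ok": "UH", "okay": "UH", "uh": "UH",
    "well": "UH",
}

_PUNCT_TAGS = {
    ".": ".", "!": ".", "?": ".", ",": ",", ":": ":", ";": ":", "--": ":",
    "(": "-LRB-", ")": "-RRB-", "``": "``", "''": "''", '"': "''",
    "$": "$", "#": "#", "-": "HYPH",
}

_NUM = re.compile(r"^\d+([.,]\d+)*$")


class RuleTagger:
    """Rule-based English tagger over the frozen 46-tag inventory.

    Closed-class lookup first, then number/punctuation detection, then
    suffix heuristics; open-class default is NN.  Intended as a fast,
    deterministic offline backend — not a statistical tagger.
    """

    def tag(self, tokens: Sequence[str]) -> list[str]:
        tags = []
        for tok in tokens:
            t = tok.lower()
            if t in _CLOSED_CLASS:
                tags.append(_CLOSED_CLASS[t])
            elif t in _PUNCT_TAGS:
                tags.append(_PUNCT_TAGS[t])
            elif _NUM.match(t):
                tags.append("CD")
            elif t.endswith("ing") and len(t) > 4:
                tags.append("VBG")
            elif t.endswith("ed") and len(t) > 3:
                tags.append("VBD")
            elif t.endswith("ly") and len(t) > 3:
                tags.append("RB")
            elif t.endswith("est") and len(t) > 4:
                tags.append("JJS")
            elif t.endswith("er") and len(t) > 3:
                tags.append("JJR")
            elif t.endswith("s") and len(t) > 3 and not t.endswith("ss"):
                tags.append("NNS")
            else:
                tags.append("NN")
        return tags


class LookupTagger:
    """Word → tag lookup table; unknown words get ``default``.  Used as the
    exact oracle backend in tests."""

    def __init__(self, table: dict[str, str], default: str = "NN") -> None:
        self.table = dict(table)
        self.default = default

    def tag(self, tokens: Sequence[str]) -> list[str]:
        return [self.table.get(t, self.default) for t in tokens]


# ---------------------------------------------------------------------------
# vocabulary / BoW

@dataclass(frozen=True)
class BowVocabulary:
    """Ordered term list; every term's corpus frequency was ≥ ``min_count``."""

    terms: tuple[str, ...]
    min_count: int

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


def build_vocab(texts: Iterable[str], min_count: int = 5) -> BowVocabulary:
    """Vocabulary of tokens with total corpus frequency ≥ ``min_count``,
    sorted lexicographically for stable indexing."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for text in texts:
        for tok in tokenize(text):
            counts[tok] = counts.get(tok, 0) + 1
    terms = tuple(sorted(t for t, c in counts.items() if c >= min_count))
    if not terms:
        raise ValueError(f"no token reaches min_count={min_count}")
    return BowVocabulary(terms=terms, min_count=min_count)


def bow_vector(text: str, vocab: BowVocabulary) -> np.ndarray:
    """Multi-hot presence vector over the vocabulary (OOV tokens ignored)."""
    index = vocab.index
    vec = np.zeros(len(vocab), dtype=np.float32)
    for tok in tokenize(text):
        i = index.get(tok)
        if i is not None:
            vec[i] = 1.0
    return vec


def pos_vector(text: str, tagger=None) -> np.ndarray:
    """46-dim tag-count vector in inventory order; the vector sums to the
    tagger's token count.  An out-of-inventory tag is a hard error."""
    tagger = tagger or RuleTagger()
    vec = np.zeros(len(TAG_INVENTORY), dtype=np.float32)
    for tag in tagger.tag(tokenize(text)):
        i = _TAG_INDEX.get(tag)
        if i is None:
            raise UnknownTagError(f"tagger emitted unknown tag {tag!r}")
        vec[i] += 1.0
    return vec


# ---------------------------------------------------------------------------
# embeddings

class HashingEmbedder:
    """Offline sentence embedder: signed feature hashing of character
    n-grams (3–5) of the lowercased text, projected to ``dim`` buckets and
    L2-normalized.  Deterministic per text; no model download."""

    def __init__(self, dim: int = 768, ngram_range: tuple[int, int] = (3, 5)) -> None:
        if dim < 1:
            raise ValueError("embedding dimension must be positive")
        self.dim = dim
        self.ngram_range = ngram_range

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float32)
        padded = f" {text.lower().strip()} "
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(max(len(padded) - n + 1, 0)):
                gram = padded[i:i + n]
                h = hashlib.blake2s(gram.encode("utf-8"), digest_size=8).digest()
                bucket = int.from_bytes(h[:4], "big") % self.dim
                sign = 1.0 if h[4] & 1 else -1.0
                vec[bucket] += sign
        norm = float(np.linalg.norm(vec))
        if norm > 0:
            vec /= norm
        return vec


class TransformerEmbedder:
    """Contract-compatible slot for a pretrained sentence encoder.  Raises
    at construction when the backing libraries are not installed."""

    def __init__(self, model_name: str = "bert-base-uncased") -> None:
        try:
            import transformers  # noqa: F401
            import torch  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "transformer embedding backend requested but the 'transformers' "
                "and 'torch' libraries are not installed"
            ) from exc
        raise NotImplementedError(
            "transformer backend wiring requires a local model checkpoint; "
            "use HashingEmbedder for offline operation"
        )


def embed(text: str, backend=None) -> np.ndarray:
    backend = backend or HashingEmbedder()
    return backend.embed(text)


# ---------------------------------------------------------------------------
# concatenation

@dataclass
class FeatureBlock:
    bow: np.ndarray
    pos: np.ndarray
    emb: np.ndarray
    concat: np.ndarray


def concat_features(bow: np.ndarray, pos: np.ndarray, emb: np.ndarray,
                    vocab_size: int | None = None,
                    emb_dim: int | None = None) -> FeatureBlock:
    """Concatenate BoW ‖ PoS ‖ embedding; dimensions are checked, never
    coerced.  Total dimension = |vocab| + 46 + E."""
    bow = np.asarray(bow, dtype=np.float32)
    pos = np.asarray(pos, dtype=np.float32)
    emb = np.asarray(emb, dtype=np.float32)
    if vocab_size is not None and bow.shape[-1] != vocab_size:
        raise ValueError(f"BoW block has dim {bow.shape[-1]}, expected {vocab_size}")
    if pos.shape[-1] != len(TAG_INVENTORY):
        raise ValueError(f"PoS block has dim {pos.shape[-1]}, expected {len(TAG_INVENTORY)}")
    if emb_dim is not None and emb.shape[-1] != emb_dim:
        raise ValueError(f"embedding block has dim {emb.shape[-1]}, expected {emb_dim}")
    return FeatureBlock(bow=bow, pos=pos, emb=emb,
                        concat=np.concatenate([bow, pos, emb], axis=-1))


def featurize_corpus(texts: Sequence[str], vocab: BowVocabulary,
                     tagger=None, embedder=None) -> np.ndarray:
    """Feature matrix (n_texts × (|vocab| + 46 + E)) for a text collection."""
    tagger = tagger or RuleTagger()
    embedder = embedder or HashingEmbedder()
    rows = []
    for text in texts:
        fb = concat_features(bow_vector(text, vocab), pos_vector(text, tagger),
                             embedder.embed(text), vocab_size=len(vocab),
                             emb_dim=embedder.dim)
        rows.append(fb.concat)
    return np.vstack(rows) if rows else np.zeros((0, len(vocab) + len(TAG_INVENTORY) + embedder.dim),
                                                 dtype=np.float32)
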