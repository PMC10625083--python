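"""Discourse-category scheme, inter-rater agreement and consensus filtering.

Eight fixed categories of depressive discourse: seven substantive themes
(dysfunctional thoughts, lifestyle challenges, social struggles, hiding
behind a mask, apathy/sadness, suicidal thoughts, seeking relief) plus a
catch-all ``etc``.  A labeled subset is annotated independently by several
raters; agreement is quantified with Fleiss kappa and items without a strong
majority are discarded before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fixed, ordered category inventory (index 0–7).
CATEGORIES: tuple[str, ...] = (
    "dysfunctional_thoughts",
    "lifestyle_challenges",
    "social_struggles",
    "hiding_behind_mask",
    "apathy_sadness",
    "suicidal_thoughts",
    "seeking_relief",
    "etc",
)

CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class AnnotationMatrix:
    """Rectangular items × raters matrix of category labels (no missing cells)."""

    items: list[str]
    labels: np.ndarray  # shape (n_items, n_raters), dtype=object (category names)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.items):
            raise ValueError("labels must be rectangular with one row per item")
        bad = {l for l in self.labels.ravel() if l not in CATEGORY_INDEX}
        if bad:
            raise ValueError(f"unknown categories in annotation matrix: {sorted(bad)}")

    @property
    def n_raters(self) -> int:
        return self.labels.shape[1]

    def counts(self) -> np.ndarray:
        """Items × categories count table (rows sum to n_raters)."""
        n_items = len(self.items)
        out = np.zeros((n_items, len(CATEGORIES)), dtype=int)
        for i in range(n_items):
            for lab in self.labels[i]:
                out[i, CATEGORY_INDEX[lab]] += 1
        return out

    def to_frame(self):
        import pandas as pd

        cols = {f"rater_{r + 1}": self.labels[:, r] for r in range(self.n_raters)}
        return pd.DataFrame({"utterance_id": self.items, **cols})

    @classmethod
    def from_frame(cls, frame) -> "AnnotationMatrix":
        rater_cols = [c for c in frame.columns if c != "utterance_id"]
        return cls(items=list(frame["utterance_id"]),
                   labels=frame[rater_cols].to_numpy(dtype=object))


@dataclass
class AgreementResult:
    kappa: float
    per_category_agreement: dict[str, float]
    degenerate: bool = False  # all assignments identical → chance agreement is 1


@dataclass
class ConsensusResult:
    kept: dict[str, str]      # utterance_id → consensus category
    discarded: list[str] = field(default_factory=list)


def fleiss_kappa(m: AnnotationMatrix) -> AgreementResult:
    """Fleiss kappa over a fixed panel of raters.

    kappa = (P̄ − P̄e) / (1 − P̄e) with P̄ the mean per-item pairwise
    agreement and P̄e the chance agreement from pooled category proportions.
    When every assignment in the matrix is the same single category, P̄e = 1
    and the ratio is 0/0; that degenerate case is reported as kappa 1 with
    ``degenerate=True``.

    ``per_category_agreement[c]`` is the probability that, given one rater
    assigned category c to an item, a second randomly chosen rater assigned
    c as well (specific agreement).
    """
    counts = m.counts()
    n_items, _ = counts.shape
    n = m.n_raters
    if n_items < 2 or n < 2:
        raise ValueError("Fleiss kappa needs >=2 items and >=2 raters")

    per_cat: dict[str, float] = {}
    for j, cat in enumerate(CATEGORIES):
        cj = counts[:, j]
        denom = int(cj.sum()) * (n - 1)
        if denom > 0:
            per_cat[cat] = float((cj * (cj - 1)).sum() / denom)

    p_cat = counts.sum(axis=0) / (n_items * n)
    if np.max(p_cat) >= 1.0:
        return AgreementResult(kappa=1.0, per_category_agreement=per_cat,
                               degenerate=True)

    from statsmodels.stats import inter_rater

    kappa = float(inter_rater.fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(kappa=kappa, per_category_agreement=per_cat)


def consensus_filter(m: AnnotationMatrix, min_agree: int = 3) -> ConsensusResult:
    """Keep items whose modal category has multiplicity ≥ ``min_agree``.

    The kept label is the modal category.  A modal tie at multiplicity ≥
    ``min_agree`` (impossible for 4 raters with the default of 3) is treated
    as disagreement and discarded.
    """
    if min_agree > m.n_raters:
        raise ValueError("min_agree cannot exceed the number of raters")
    counts = m.counts()
    kept: dict[str, str] = {}
    discarded: list[str] = []
    for i, item in enumerate(m.items):
        top = counts[i].max()
        modal = [CATEGORIES[j] for j in np.flatnonzero(counts[i] == top)]
        if top >= min_agree and len(modal) == 1:
            kept[item] = modal[0]
        else:
            discarded.append(item)
    return ConsensusResult(kept=kept, discarded=discarded)
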