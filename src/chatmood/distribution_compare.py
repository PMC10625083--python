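"""Category-share tables, East-vs-West chi-square tests, and comparison
against a packaged cross-platform (Twitter) reference distribution.

Percentages are rounded half-up to 2 decimal places, matching how shares
are conventionally printed; raw counts are always retained so no statistic
is ever computed from rounded numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import chi2_contingency

from .annotation import CATEGORIES


def round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategoryDistribution:
    group: str
    counts: dict[str, int]
    total: int = 0
    percent: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total == 0:
            self.total = sum(self.counts.values())
        if self.total <= 0:
            raise ValueError("distribution total must be positive")
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts must sum to total")
        if not self.percent:
            self.percent = {c: round_half_up(100.0 * n / self.total, 2)
                            for c, n in self.counts.items()}


@dataclass
class ChiSquareResult:
    category: str
    statistic: float
    df: int
    p: float
    unreliable: bool = False  # some expected cell < 1


def category_shares(labels: Mapping[str, str],
                    groups: Mapping[str, str]) -> dict[str, CategoryDistribution]:
    """Per-group exact category counts and 2-dp percentage shares.

    ``labels`` maps utterance id → category; ``groups`` maps utterance id →
    group name (e.g. region).  Every label must be a valid category.
    """
    bad = {c for c in labels.values() if c not in CATEGORIES}
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    table: dict[str, dict[str, int]] = {}
    for utt, cat in labels.items():
        grp = groups[utt]
        table.setdefault(grp, {c: 0 for c in CATEGORIES})[cat] += 1
    return {g: CategoryDistribution(group=g, counts=cnt) for g, cnt in table.items()}


def per_category_chi_square(dist_a: CategoryDistribution,
                            dist_b: CategoryDistribution) -> list[ChiSquareResult]:
    """Pearson chi-square per category on the 2×2 table
    [in-category vs not] × [group A vs B], df=1, no continuity correction."""
    out = []
    for cat in CATEGORIES:
        a_in = dist_a.counts.get(cat, 0)
        b_in = dist_b.counts.get(cat, 0)
        table = np.array([[a_in, dist_a.total - a_in],
                          [b_in, dist_b.total - b_in]], dtype=float)
        if a_in == b_in == 0:
            out.append(ChiSquareResult(cat, 0.0, 1, 1.0, unreliable=True))
            continue
        stat, p, df, expected = chi2_contingency(table, correction=False)
        out.append(ChiSquareResult(category=cat, statistic=float(stat), df=int(df),
                                   p=float(p), unreliable=bool(expected.min() < 1)))
    return out


def overall_chi_square(dist_a: CategoryDistribution,
                       dist_b: CategoryDistribution) -> ChiSquareResult:
    """Single 2×8 Pearson test of the whole category distribution."""
    table = np.array([[dist_a.counts.get(c, 0) for c in CATEGORIES],
                      [dist_b.counts.get(c, 0) for c in CATEGORIES]], dtype=float)
    keep = table.sum(axis=0) > 0
    stat, p, df, expected = chi2_contingency(table[:, keep], correction=False)
    return ChiSquareResult(category="(overall)", statistic=float(stat), df=int(df),
                           p=float(p), unreliable=bool(expected.min() < 1))


@dataclass
class ReferenceDistribution:
    """Shares borrowed from another platform's printed analysis; only cells
    with a cited printed source are present."""

    platform: str
    percent: dict[str, float]
    provenance: dict[str, str]
    flagged: frozenset[str] = frozenset()


def load_twitter_reference() -> ReferenceDistribution:
    ref = resources.files("chatmood.data").joinpath("twitter_reference.json")
    raw = json.loads(ref.read_text(encoding="utf-8"))
    cells = raw["cells"]
    return ReferenceDistribution(
        platform=raw["platform"],
        percent={c: v["percent"] for c, v in cells.items()},
        provenance={c: v["provenance"] for c, v in cells.items()},
        flagged=frozenset(c for c, v in cells.items() if v.get("discrepancy")),
    )


def compare_to_reference(dist: CategoryDistribution,
                         ref: ReferenceDistribution) -> list[dict]:
    """Side-by-side percentage comparison; categories absent from the
    reference appear with ``ref_percent`` None and no imputed difference."""
    rows = []
    for cat in CATEGORIES:
        own = dist.percent.get(cat, 0.0)
        other = ref.percent.get(cat)
        rows.append({
            "category": cat,
            "own_percent": own,
            "ref_percent": other,
            "difference": None if other is None else round_half_up(own - other, 2),
            "ref_provenance": ref.provenance.get(cat),
        })
    return rows


def render_report(sections: Mapping[str, object], seed: int | None = None,
                  config_hash: str | None = None) -> tuple[str, dict]:
    """Render results as markdown plus a JSON-serializable machine table.

    Same inputs → byte-identical output.  The header always records the
    seed, config hash and package version for reproducibility.
    """
    from . import __version__

    machine: dict[str, object] = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash,
    }
    lines = ["# chatmood report", "",
             f"- package version: {__version__}",
             f"- seed: {seed}",
             f"- config hash: {config_hash}", ""]
    if not sections:
        lines += ["## no results", "", "No analysis sections were provided.", ""]
    for name, payload in sections.items():
        lines += [f"## {name}", ""]
        machine[name] = _jsonable(payload)
        lines.append("```json")
        lines.append(json.dumps(machine[name], indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    return "\n".join(lines), machine


def _jsonable(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj
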