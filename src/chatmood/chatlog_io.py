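"""Chat-log corpus I/O, keyword filtering, region mapping, sampling and PII masking.

A corpus is a flat list of :class:`ChatRecord` — one user↔bot exchange each,
carrying the user's country (mapped deterministically to an Eastern/Western
cultural region) and a local wall-clock timestamp.  Corpora are stored as
JSONL (one object per line) or TSV (tab-separated, header row, UTF-8).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

EASTERN = "Eastern"
WESTERN = "Western"

#: Deterministic country → cultural-region table for the eight study countries.
#: Both full names and ISO 3166 alpha-2 codes are accepted (case-insensitive).
REGION_TABLE: dict[str, str] = {
    "malaysia": EASTERN, "my": EASTERN,
    "philippines": EASTERN, "the philippines": EASTERN, "ph": EASTERN,
    "india": EASTERN, "in": EASTERN,
    "indonesia": EASTERN, "id": EASTERN,
    "thailand": EASTERN, "th": EASTERN,
    "canada": WESTERN, "ca": WESTERN,
    "united kingdom": WESTERN, "the united kingdom": WESTERN, "gb": WESTERN, "uk": WESTERN,
    "united states": WESTERN, "the united states": WESTERN, "us": WESTERN, "usa": WESTERN,
}

_TS_FORMAT = "%Y-%m-%d %H:%M:%S"
_FIELDS = ("utterance_id", "user_id", "country", "timestamp", "user_text", "bot_text")


class UnknownCountryError(ValueError):
    """Raised for a country absent from the region table (no silent default)."""


@dataclass(frozen=True)
class ChatRecord:
    """One user↔bot exchange.

    ``region`` is always the deterministic image of ``country`` under
    :func:`map_region`; ``timestamp`` is local wall-clock time (hour
    resolution is what downstream temporal analysis uses).
    """

    utterance_id: str
    user_id: str
    country: str
    region: str
    timestamp: datetime
    user_text: str
    bot_text: str = ""

    def __post_init__(self) -> None:
        if not self.user_text.strip():
            raise ValueError("user_text must be non-empty after whitespace trim")
        if self.region != map_region(self.country):
            raise ValueError(
                f"region {self.region!r} inconsistent with country {self.country!r}"
            )


@dataclass(frozen=True)
class KeywordSet:
    """Named ordered set of lowercase keyword phrases (may contain spaces)."""

    name: str
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError("keyword set must be non-empty")
        if len(set(self.phrases)) != len(self.phrases):
            raise ValueError("keyword phrases must be unique")
        for p in self.phrases:
            if not p or p != p.lower():
                raise ValueError(f"keyword phrase must be non-empty lowercase: {p!r}")


@dataclass
class ReadResult:
    """Records parsed from a corpus file plus per-line error reports."""

    records: list[ChatRecord]
    errors: list[tuple[int, str]]  # (1-based line number, message)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def map_region(country: str) -> str:
    """Map one of the eight study countries to ``Eastern`` or ``Western``.

    Raises :class:`UnknownCountryError` for any unlisted country.
    """
    key = country.strip().lower()
    try:
        return REGION_TABLE[key]
    except KeyError:
        raise UnknownCountryError(
            f"country {country!r} is not in the study region table"
        ) from None


def load_keyword_set(name: str) -> KeywordSet:
    """Load a packaged keyword set (``depressed_sad`` or ``happy_excited``)."""
    ref = resources.files("chatmood.data.keywords").joinpath(f"{name}.txt")
    phrases = tuple(
        line.strip() for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    return KeywordSet(name=name, phrases=phrases)


def filter_by_keywords(records: Iterable[ChatRecord], keys: KeywordSet) -> list[ChatRecord]:
    """Keep records whose lowercased ``user_text`` contains ≥1 phrase.

    Matching is raw case-insensitive substring search, so the stem
    ``"depress"`` hits "depressed", "depression", etc.  Order is preserved;
    the result may be empty.
    """
    out = []
    for rec in records:
        text = rec.user_text.lower()
        if any(p in text for p in keys.phrases):
            out.append(rec)
    return out


def sample_one_per_user(records: Sequence[ChatRecord], seed: int) -> list[ChatRecord]:
    """Pick exactly one record per distinct ``user_id``, uniformly at random.

    Reproducible for a fixed seed.  Output is ordered by first appearance of
    each user in the input.
    """
    import numpy as np

    by_user: dict[str, list[ChatRecord]] = {}
    for rec in records:
        by_user.setdefault(rec.user_id, []).append(rec)
    rng = np.random.default_rng(seed)
    return [group[int(rng.integers(len(group)))] for group in by_user.values()]


def mask_pii(text: str, min_run: int = 4) -> str:
    """Replace every maximal run of ≥ ``min_run`` consecutive digits with
    asterisks of equal length.  Length-preserving and idempotent."""
    pattern = re.compile(rf"\d{{{min_run},}}")
    return pattern.sub(lambda m: "*" * len(m.group()), text)


def _record_from_fields(fields: dict) -> ChatRecord:
    missing = [f for f in _FIELDS if f not in fields or fields[f] is None]
    # bot_text may be empty but the key must exist for the 5 source fields;
    # tolerate an absent bot_text as empty string.
    if "bot_text" in missing:
        missing.remove("bot_text")
        fields = {**fields, "bot_text": ""}
    if missing:
        raise ValueError(f"missing required field(s): {', '.join(missing)}")
    ts = fields["timestamp"]
    if not isinstance(ts, datetime):
        ts = datetime.strptime(str(ts), _TS_FORMAT)
    return ChatRecord(
        utterance_id=str(fields["utterance_id"]),
        user_id=str(fields["user_id"]),
        country=str(fields["country"]),
        region=map_region(str(fields["country"])),
        timestamp=ts,
        user_text=str(fields["user_text"]),
        bot_text=str(fields["bot_text"]),
    )


def read_corpus(path: str | Path, format: str | None = None) -> ReadResult:
    """Read a JSONL or TSV corpus; malformed lines are reported, not fatal.

    ``format`` defaults from the file suffix (``.jsonl``/``.tsv``).  Each
    error is recorded as ``(line_number, message)``; unknown countries and
    missing fields are record-level errors.
    """
    path = Path(path)
    fmt = format or ("tsv" if path.suffix == ".tsv" else "jsonl")
    records: list[ChatRecord] = []
    errors: list[tuple[int, str]] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if fmt == "jsonl":
        for i, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                records.append(_record_from_fields(json.loads(line)))
            except (json.JSONDecodeError, ValueError, UnknownCountryError) as exc:
                errors.append((i, str(exc)))
    elif fmt == "tsv":
        if not lines:
            return ReadResult([], [])
        header = lines[0].split("\t")
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                errors.append((i, f"expected {len(header)} fields, got {len(parts)}"))
                continue
            try:
                records.append(_record_from_fields(dict(zip(header, parts))))
            except (ValueError, UnknownCountryError) as exc:
                errors.append((i, str(exc)))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    return ReadResult(records, errors)


def write_corpus(records: Iterable[ChatRecord], path: str | Path,
                 format: str | None = None) -> None:
    """Write records as JSONL or TSV (tabs/newlines in text become spaces)."""
    path = Path(path)
    fmt = format or ("tsv" if path.suffix == ".tsv" else "jsonl")
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        if fmt == "jsonl":
            for rec in records:
                row = dataclasses.asdict(rec)
                row["timestamp"] = rec.timestamp.strftime(_TS_FORMAT)
                row.pop("region")  # derived field, recomputed on read
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
        elif fmt == "tsv":
            clean = re.compile(r"[\t\r\n]")
            fh.write("\t".join(_FIELDS) + "\n")
            for rec in records:
                vals = [
                    rec.utterance_id, rec.user_id, rec.country,
                    rec.timestamp.strftime(_TS_FORMAT),
                    clean.sub(" ", rec.user_text), clean.sub(" ", rec.bot_text),
                ]
                fh.write("\t".join(vals) + "\n")
        else:
            raise ValueError(f"unknown corpus format {fmt!r}")
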