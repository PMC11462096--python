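"""Dictionary normalization of symptom surface forms by Levenshtein distance.

Extracted surface forms are noisy: the same symptom appears as しびれ,
しびれ感, 末梢神経障害, etc.  Normalization maps each surface form onto a
canonical symptom term by finding the dictionary surface form with the lowest
Levenshtein distance (unit-cost insertions, deletions, substitutions over
Unicode code points) and returning its associated normalized form.

Both query and dictionary surfaces are canonicalized before any distance is
computed: NFKC compatibility normalization (which unifies full-width and
half-width variants), surrounding-whitespace trimming, and lower-casing of
ASCII segments only — Japanese text has no case, and aggressive folding of
non-Latin scripts would silently change distances.

Minimum-distance matching can tie.  Ties are broken by, in order:

1. largest character-alignment overlap with the query (LCS length) — of two
   equally distant candidates, prefer the one that shares actual content;
2. shorter dictionary surface;
3. lexicographic order of the surface.

This makes matching deterministic across runs and platforms, and lets a
four-character query that shares a two-character stem with one candidate beat
unrelated candidates at the same raw distance.
"""

from __future__ import annotations

import datetime
import logging
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .corpus import DocType
from .extract import Mention

__all__ = [
    "DictionaryEntry",
    "NormalizationDictionary",
    "NormalizationResult",
    "NormalizedEvent",
    "DictionaryError",
    "canonical",
    "levenshtein",
    "lcs_length",
    "load_dictionary",
    "fixture_dictionary",
    "normalize_mention",
    "normalize_all",
]

logger = logging.getLogger(__name__)


class DictionaryError(ValueError):
    """Raised for invalid normalization dictionaries."""


def canonical(s: str) -> str:
    """Canonicalize text for distance computation (NFKC, strip, ASCII lower)."""
    s = unicodedata.normalize("NFKC", s).strip()
    return "".join(c.lower() if c.isascii() else c for c in s)


def levenshtein(a: str, b: str) -> int:
    """Classic edit distance: unit-cost insert/delete/substitute on code points."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence (alignment overlap)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class DictionaryEntry:
    surface: str
    normalized: str

    def __post_init__(self) -> None:
        if not canonical(self.surface) or not canonical(self.normalized):
            raise DictionaryError(
                f"entry ({self.surface!r}, {self.normalized!r}) empty after canonicalization"
            )


@dataclass(frozen=True)
class NormalizationDictionary:
    """Surface-form -> normalized-form dictionary with recorded canonicalization."""

    entries: tuple[DictionaryEntry, ...]
    canonicalization: str = "nfkc-strip-ascii-lower"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            key = canonical(e.surface)
            if key in seen and seen[key] != e.normalized:
                raise DictionaryError(
                    f"surface {e.surface!r} maps to both {seen[key]!r} and {e.normalized!r}"
                )
            seen[key] = e.normalized

    @property
    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]


def load_dictionary(path) -> NormalizationDictionary:
    """Load a two-column TSV (surface TAB normalized, UTF-8, no header).

    Duplicate identical rows collapse to one entry; the same surface mapping
    to two different normalized forms is a load error naming the surface.
    An empty file is an error.
    """
    entries: list[DictionaryEntry] = []
    seen_pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DictionaryError(f"{path}:{lineno}: expected 2 tab-separated columns")
            surface, normalized = parts
            pair = (canonical(surface), normalized)
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            entries.append(DictionaryEntry(surface=surface, normalized=normalized))
    if not entries:
        raise DictionaryError(f"{path}: dictionary is empty")
    return NormalizationDictionary(entries=tuple(entries))


def fixture_dictionary() -> NormalizationDictionary:
    """The small bundled symptom dictionary (synthetic stand-in).

    A hand-built fixture covering peripheral-neuropathy surface forms and a
    few distractor symptoms; it is a synthetic, desk-scale stand-in for a full
    cancer-ADE normalization dictionary, which users supply as a TSV.
    """
    path = Path(__file__).parent / "data" / "fixture_dictionary.tsv"
    return load_dictionary(path)


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of matching one surface form against the dictionary."""

    normalized: str
    matched_surface: str
    distance: int


def normalize_mention(
    surface: str,
    dictionary: NormalizationDictionary,
    max_distance: Optional[int] = None,
) -> Optional[NormalizationResult]:
    """Match ``surface`` to the dictionary entry at minimum Levenshtein distance.

    Returns ``None`` (no-match) when ``max_distance`` is set and the minimum
    distance exceeds it.  An exact dictionary surface always matches at
    distance 0 regardless of ``max_distance``.  With ``max_distance=0`` this
    is exact dictionary lookup.
    """
    if not dictionary.entries:
        raise DictionaryError("dictionary is empty")
    query = canonical(surface)
    best: Optional[tuple[int, int, int, str, DictionaryEntry]] = None
    for entry in dictionary.entries:
        cand = canonical(entry.surface)
        d = levenshtein(query, cand)
        key = (d, -lcs_length(query, cand), len(cand), cand, entry)
        if best is None or key[:4] < best[:4]:
            best = key
    assert best is not None
    distance, _, _, _, entry = best
    if max_distance is not None and distance > max_distance:
        return None
    return NormalizationResult(
        normalized=entry.normalized, matched_surface=entry.surface, distance=distance
    )


@dataclass(frozen=True)
class NormalizedEvent:
    """A dated, document-typed occurrence of a normalized symptom term."""

    patient_id: str
    doc_type: DocType
    date: datetime.date
    normalized: str
    surface: str
    distance: int


def normalize_all(
    mentions: Sequence[Mention],
    dictionary: NormalizationDictionary,
    max_distance: Optional[int] = None,
) -> list[NormalizedEvent]:
    """Normalize a batch of (already factuality-filtered) mentions.

    No-matches are dropped; their count is logged so a threshold that is too
    tight is visible in the run log rather than silent.
    """
    events: list[NormalizedEvent] = []
    dropped = 0
    for m in mentions:
        result = normalize_mention(m.surface, dictionary, max_distance=max_distance)
        if result is None:
            dropped += 1
            continue
        events.append(
            NormalizedEvent(
                patient_id=m.patient_id,
                doc_type=m.doc_type,
                date=m.date,
                normalized=result.normalized,
                surface=m.surface,
                distance=result.distance,
            )
        )
    if dropped:
        logger.info("normalize_all: dropped %d mention(s) beyond max_distance", dropped)
    return events
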