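"""Symptom-mention extraction with factuality labelling.

Two routes produce :class:`Mention` objects:

* a built-in lexicon/rule tagger (:func:`tag_mentions`) — a transparent,
  desk-scale stand-in for a transformer NER model.  It scans each passage for
  dictionary surface forms (longest match, left to right, non-overlapping) and
  assigns a factuality label from cue words in the same passage; or
* an adapter (:func:`load_external_mentions`) that imports the output of an
  external NER model and validates it against the corpus.

Factuality matters because clinical text mentions symptoms that did *not*
occur: negated findings ("しびれなし") and risk/consent explanations
("副作用のリスクについて説明").  Only mentions with *positive* factuality count
as adverse-event evidence downstream; :func:`filter_positive` applies that rule.

Long records are first cut into passages (:func:`split_passages`) so that each
unit handed to a tagger stays under a character budget — the analogue of a
transformer's fixed input window.  The primary cut is at line breaks, because
clinical notes put one statement per line; oversized lines fall back to
sentence-final punctuation, then to a hard cut.
"""

from __future__ import annotations

import datetime
import enum
import json
from dataclasses import dataclass

from typing import Iterable, Sequence

from .corpus import Corpus, CorpusFormatError, DocType, DocumentRecord, _coerce_enum, _parse_date

__all__ = [
    "Factuality",
    "Mention",
    "TaggerConfig",
    "split_passages",
    "tag_mentions",
    "tag_corpus",
    "load_external_mentions",
    "filter_positive",
    "DEFAULT_NEGATION_CUES",
    "DEFAULT_RISK_CUES",
]

# Cue inventories mirror the false-positive classes seen in clinical notes:
# negated findings, and risk/side-effect counselling statements.
DEFAULT_NEGATION_CUES: tuple[str, ...] = ("なし", "ない", "認めず", "認めない", "ません")
DEFAULT_RISK_CUES: tuple[str, ...] = ("リスク", "おそれ", "について説明", "副作用")

_SENTENCE_ENDERS = "。．.!?！？"


class Factuality(str, enum.Enum):
    """Whether a mentioned symptom actually occurred."""

    positive = "positive"
    negative = "negative"
    suspected = "suspected"
    general = "general"


@dataclass(frozen=True)
class Mention:
    """A character-span symptom expression in one record, with factuality.

    Offsets are 0-based half-open in whole-record coordinates; ``surface``
    must equal the covered substring of the record text.
    """

    patient_id: str
    doc_type: DocType
    date: datetime.date
    start: int
    end: int
    surface: str
    factuality: Factuality

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if not isinstance(self.factuality, Factuality):
            object.__setattr__(
                self, "factuality", _coerce_enum(Factuality, self.factuality, "factuality")
            )
        if not isinstance(self.doc_type, DocType):
            object.__setattr__(self, "doc_type", _coerce_enum(DocType, self.doc_type, "doc_type"))
        object.__setattr__(self, "date", _parse_date(self.date, "Mention"))


@dataclass(frozen=True)
class TaggerConfig:
    """Configuration for the built-in lexicon/rule tagger.

    ``passage_char_budget`` caps passage length in characters (default 500),
    honouring the fixed-window contract of transformer taggers without tying
    the package to any specific tokenizer.  When both a negation cue and a
    risk cue occur in one passage, negation wins (label ``negative``): the
    tie-break is deterministic and documented here.
    """

    lexicon: frozenset[str]
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    risk_explanation_cues: tuple[str, ...] = DEFAULT_RISK_CUES
    passage_char_budget: int = 500

    def __post_init__(self) -> None:
        if not self.lexicon:
            raise ValueError("lexicon must be non-empty for the built-in tagger")
        object.__setattr__(self, "lexicon", frozenset(self.lexicon))
        longest = max(len(s) for s in self.lexicon)
        if self.passage_char_budget < longest:
            raise ValueError(
                f"passage_char_budget {self.passage_char_budget} shorter than "
                f"longest lexicon entry ({longest} chars)"
            )


def split_passages(text: str, budget: int) -> list[tuple[str, int]]:
    """Split ``text`` into passages of at most ``budget`` characters.

    Returns ``(passage, offset)`` pairs where ``offset`` indexes the passage
    start in the original text.  Splits at line breaks first; a single line
    longer than the budget is further split at sentence-final punctuation and,
    as a last resort, at the budget boundary.  Concatenating the passages with
    the skipped separators reconstructs the original text exactly.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    out: list[tuple[str, int]] = []
    pos = 0
    for line in text.split("\n"):
        if line:
            out.extend(_split_line(line, pos, budget))
        pos += len(line) + 1  # account for the consumed '\n'
    return out


def _split_line(line: str, base: int, budget: int) -> Iterable[tuple[str, int]]:
    start = 0
    n = len(line)
    while n - start > budget:
        window = line[start : start + budget]
        cut = -1
        for i in range(len(window) - 1, -1, -1):
            if window[i] in _SENTENCE_ENDERS:
                cut = i + 1  # keep the punctuation with the left chunk
                break
        if cut <= 0:
            cut = budget
        yield line[start : start + cut], base + start
        start += cut
    if start < n:
        yield line[start:], base + start


def _match_factuality(passage: str, config: TaggerConfig) -> Factuality:
    # Passage-scoped cue logic; negation outranks risk/explanation cues.
    if any(cue in passage for cue in config.negation_cues):
        return Factuality.negative
    if any(cue in passage for cue in config.risk_explanation_cues):
        return Factuality.suspected
    return Factuality.positive


def tag_mentions(record: DocumentRecord, config: TaggerConfig) -> list[Mention]:
    """Tag lexicon surface forms in one record.

    Longest-match, non-overlapping, left-to-right scan within each passage;
    spans are reported in whole-record coordinates with no text mutation, so
    ``record.text[m.start:m.end] == m.surface`` always holds.
    """
    by_length = sorted(config.lexicon, key=len, reverse=True)
    mentions: list[Mention] = []
    for passage, offset in split_passages(record.text, config.passage_char_budget):
        factuality = _match_factuality(passage, config)
        i = 0
        while i < len(passage):
            hit = next((s for s in by_length if passage.startswith(s, i)), None)
            if hit is None:
                i += 1
                continue
            mentions.append(
                Mention(
                    patient_id=record.patient_id,
                    doc_type=record.doc_type,
                    date=record.timestamp,
                    start=offset + i,
                    end=offset + i + len(hit),
                    surface=hit,
                    factuality=factuality,
                )
            )
            i += len(hit)
    return mentions


def tag_corpus(corpus: Corpus, config: TaggerConfig,
               patient_ids: set[str] | None = None) -> list[Mention]:
    """Tag every record in a corpus (optionally restricted to some patients)."""
    out: list[Mention] = []
    for record in corpus.records:
        if patient_ids is not None and record.patient_id not in patient_ids:
            continue
        out.extend(tag_mentions(record, config))
    return out


def load_external_mentions(path, corpus: Corpus) -> list[Mention]:
    """Import mentions produced by an external NER model (JSONL adapter).

    Each line carries ``patient_id, doc_type, timestamp, start, end, surface,
    factuality``.  Every mention is validated against the corpus: the span
    must lie inside the referenced record's text and the surface must equal
    the covered substring (this guards against offset-convention drift between
    the external model and this package).  Unknown factuality strings raise an
    error listing the accepted values.
    """
    index: dict[tuple[str, str, str], DocumentRecord] = {}
    for r in corpus.records:
        index[(r.patient_id, r.doc_type.value, r.timestamp.isoformat())] = r

    mentions: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed JSON line") from exc
            key = (obj["patient_id"], obj["doc_type"], str(obj["timestamp"])[:10])
            record = index.get(key)
            if record is None:
                raise CorpusFormatError(f"{path}:{lineno}: no corpus record matching {key}")
            start, end = int(obj["start"]), int(obj["end"])
            if not (0 <= start < end <= len(record.text)):
                raise CorpusFormatError(
                    f"{path}:{lineno}: span [{start}, {end}) outside text of record {key} "
                    f"(length {len(record.text)})"
                )
            covered = record.text[start:end]
            if covered != obj["surface"]:
                raise CorpusFormatError(
                    f"{path}:{lineno}: surface {obj['surface']!r} disagrees with "
                    f"text[{start}:{end}] == {covered!r} in record {key}"
                )
            if obj["factuality"] not in Factuality._value2member_map_:
                accepted = ", ".join(f.value for f in Factuality)
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown factuality {obj['factuality']!r}; "
                    f"accepted values: {accepted}"
                )
            mentions.append(
                Mention(
                    patient_id=record.patient_id,
                    doc_type=record.doc_type,
                    date=record.timestamp,
                    start=start,
                    end=end,
                    surface=covered,
                    factuality=Factuality(obj["factuality"]),
                )
            )
    return mentions


def filter_positive(mentions: Sequence[Mention]) -> list[Mention]:
    """Keep exactly the mentions with positive factuality, order preserved."""
    return [m for m in mentions if m.factuality is Factuality.positive]
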