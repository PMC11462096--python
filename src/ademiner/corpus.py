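"""Domain types for the document corpus and line-delimited JSON readers/writers.

A corpus is the raw material of the pipeline: per-patient timestamped free-text
records of six clinical document types (written by physicians, nurses,
pharmacists, radiologists, ...) plus structured medication orders of two types
(injection and medicine).  Text fields routinely contain line breaks, so the
on-disk format is one JSON object per line (JSONL) rather than CSV: JSON string
escaping makes the round trip lossless without any bespoke quoting rules.

Dates are ISO-8601 calendar dates; intra-day time is deliberately discarded
because every downstream quantity (onset day, duration, censoring) is counted
in whole days.  Patient identifiers are opaque strings.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "DocType",
    "OrderType",
    "DocumentRecord",
    "MedicationOrder",
    "Corpus",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "corpus_summary",
]


class DocType(str, Enum):
    """The six clinical document types handled by the pipeline."""

    physician_note = "physician_note"
    nursing_record = "nursing_record"
    discharge_summary = "discharge_summary"
    radiology_report = "radiology_report"
    radioisotope_report = "radioisotope_report"
    pharmacist_note = "pharmacist_note"


class OrderType(str, Enum):
    """The two structured medication-order types."""

    injection = "injection"
    medicine = "medicine"


class CorpusFormatError(ValueError):
    """Raised for malformed or invalid corpus files."""


def _parse_date(value: Union[str, datetime.date], context: str) -> datetime.date:
    if isinstance(value, datetime.date) and not isinstance(value, datetime.datetime):
        return value
    try:
        return datetime.date.fromisoformat(str(value)[:10])
    except ValueError as exc:
        raise CorpusFormatError(f"{context}: invalid ISO date {value!r}") from exc


@dataclass(frozen=True)
class DocumentRecord:
    """One timestamped free-text record of one document type for one patient."""

    patient_id: str
    doc_type: DocType
    timestamp: datetime.date
    text: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CorpusFormatError("patient_id must be a non-empty string")
        if not isinstance(self.doc_type, DocType):
            object.__setattr__(self, "doc_type", _coerce_enum(DocType, self.doc_type, "doc_type"))
        object.__setattr__(self, "timestamp", _parse_date(self.timestamp, "DocumentRecord"))
        if self.text is None:
            raise CorpusFormatError("text may be empty but not absent")


@dataclass(frozen=True)
class MedicationOrder:
    """One structured medication order (one drug, one date) for one patient."""

    patient_id: str
    order_type: OrderType
    drug_name: str
    date: datetime.date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CorpusFormatError("patient_id must be a non-empty string")
        if not isinstance(self.order_type, OrderType):
            object.__setattr__(
                self, "order_type", _coerce_enum(OrderType, self.order_type, "order_type")
            )
        if not self.drug_name:
            raise CorpusFormatError("drug_name must be non-empty")
        object.__setattr__(self, "date", _parse_date(self.date, "MedicationOrder"))


def _coerce_enum(enum_cls, value, field_name):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise CorpusFormatError(
            f"unknown {field_name} {value!r}; expected one of: {allowed}"
        ) from None


@dataclass
class Corpus:
    """A collection of document records plus medication orders."""

    records: list[DocumentRecord] = field(default_factory=list)
    orders: list[MedicationOrder] = field(default_factory=list)

    @property
    def patient_ids(self) -> set[str]:
        return {r.patient_id for r in self.records} | {o.patient_id for o in self.orders}

    def records_for(self, patient_id: str) -> list[DocumentRecord]:
        return [r for r in self.records if r.patient_id == patient_id]


_RECORD_KEYS = ("patient_id", "doc_type", "timestamp", "text")
_ORDER_KEYS = ("patient_id", "order_type", "drug_name", "date")


def _read_jsonl(path: Path, keys: tuple[str, ...]) -> Iterable[dict]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed JSON line") from exc
            missing = [k for k in keys if k not in obj]
            if missing:
                raise CorpusFormatError(f"{path}:{lineno}: missing keys {missing}")
            yield obj


def read_corpus(records_path, orders_path) -> Corpus:
    """Read a corpus from a JSONL records file and a JSONL orders file.

    Records with an unknown ``doc_type`` or ``order_type`` raise
    :class:`CorpusFormatError` naming the offending value; they are never
    silently dropped.  Missing files raise ``FileNotFoundError``.
    """
    records = [
        DocumentRecord(o["patient_id"], o["doc_type"], o["timestamp"], o["text"])
        for o in _read_jsonl(Path(records_path), _RECORD_KEYS)
    ]
    orders = [
        MedicationOrder(o["patient_id"], o["order_type"], o["drug_name"], o["date"])
        for o in _read_jsonl(Path(orders_path), _ORDER_KEYS)
    ]
    return Corpus(records=records, orders=orders)


def write_corpus(corpus: Corpus, records_path, orders_path) -> None:
    """Write a corpus as two JSONL files; inverse of :func:`read_corpus`."""
    with open(records_path, "w", encoding="utf-8") as fh:
        for r in corpus.records:
            fh.write(
                json.dumps(
                    {
                        "patient_id": r.patient_id,
                        "doc_type": r.doc_type.value,
                        "timestamp": r.timestamp.isoformat(),
                        "text": r.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(orders_path, "w", encoding="utf-8") as fh:
        for o in corpus.orders:
            fh.write(
                json.dumps(
                    {
                        "patient_id": o.patient_id,
                        "order_type": o.order_type.value,
                        "drug_name": o.drug_name,
                        "date": o.date.isoformat(),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def corpus_summary(corpus: Corpus) -> pd.DataFrame:
    """Count records per document type and orders per order type.

    Returns a tidy table with columns ``kind`` (text/order), ``record_type``
    and ``count``.  Every document type and order type appears (zero-filled),
    so the table shape is stable regardless of corpus content.
    """
    doc_counts = {dt.value: 0 for dt in DocType}
    for r in corpus.records:
        doc_counts[r.doc_type.value] += 1
    order_counts = {ot.value: 0 for ot in OrderType}
    for o in corpus.orders:
        order_counts[o.order_type.value] += 1
    rows = [("order", k, v) for k, v in order_counts.items()]
    rows += [("text", k, v) for k, v in doc_counts.items()]
    return pd.DataFrame(rows, columns=["kind", "record_type", "count"])
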