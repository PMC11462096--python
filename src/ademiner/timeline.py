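"""Cohort selection and per-patient event timelines.

The exposure cohort is defined by *exclusive* drug exposure: a patient belongs
to arm A if they have at least one medication order matching the arm-A drug
names and none matching arm B (and symmetrically); patients exposed to both
drugs are excluded because a second neurotoxic agent started mid-follow-up
would confound onset and duration, and patients exposed to neither are out of
scope.  Drug-name matching is exact on canonicalized strings against an
explicit configured name list (generic plus brand names) — substring matching
over order text is deliberately avoided because it invites silent false
exposure.

Each included patient is anchored at the date of their first matching dose
(day 0).  Normalized events are converted to whole-day indices since first
dose; the onset day is the first day on which the target term appears in any
document type, the last day is the latest such day, and duration is their
difference.  Mentions dated before the first dose cannot be attributed to the
drug; they are excluded from the timeline but counted, so an audit can see
how many were dropped.  A patient with no event is censored at their last
contact: the latest record of any document type.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .corpus import DocType, DocumentRecord, MedicationOrder
from .normalize import NormalizedEvent, canonical

__all__ = [
    "CohortSelection",
    "TimelineEvent",
    "PatientTimeline",
    "OnsetSummary",
    "select_cohort",
    "first_dose_date",
    "build_timeline",
    "build_cohort_timelines",
    "onset_and_duration",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSelection:
    """Partition of the patient universe by exclusive drug exposure."""

    arm_a_patients: frozenset[str]
    arm_b_patients: frozenset[str]
    excluded_both: frozenset[str]
    excluded_neither: frozenset[str]

    @property
    def included(self) -> frozenset[str]:
        return self.arm_a_patients | self.arm_b_patients


@dataclass(frozen=True)
class TimelineEvent:
    day_index: int
    doc_type: DocType
    normalized: str


@dataclass(frozen=True)
class PatientTimeline:
    """First-dose-anchored sequence of target-term events for one patient."""

    patient_id: str
    first_dose_date: datetime.date
    events: tuple[TimelineEvent, ...]
    followup_end_day: int
    n_pre_dose_dropped: int = 0

    def __post_init__(self) -> None:
        days = [e.day_index for e in self.events]
        if days != sorted(days):
            object.__setattr__(
                self, "events", tuple(sorted(self.events, key=lambda e: (e.day_index, e.doc_type.value)))
            )
        if self.events and self.events[-1].day_index > self.followup_end_day:
            raise ValueError("event beyond follow-up end")

    def restricted_to(self, doc_types: Iterable[DocType]) -> "PatientTimeline":
        """The same timeline keeping only events from the given document types."""
        allowed = set(doc_types)
        return PatientTimeline(
            patient_id=self.patient_id,
            first_dose_date=self.first_dose_date,
            events=tuple(e for e in self.events if e.doc_type in allowed),
            followup_end_day=self.followup_end_day,
            n_pre_dose_dropped=self.n_pre_dose_dropped,
        )


@dataclass(frozen=True)
class OnsetSummary:
    """Onset/last-detection/duration triple; all present or all absent."""

    onset_day: Optional[int]
    last_day: Optional[int]
    duration_days: Optional[int]

    def __post_init__(self) -> None:
        present = [self.onset_day is not None, self.last_day is not None,
                   self.duration_days is not None]
        if any(present) and not all(present):
            raise ValueError("onset/last/duration must all be present or all absent")
        if self.onset_day is not None:
            if self.duration_days != self.last_day - self.onset_day or self.duration_days < 0:
                raise ValueError("duration must equal last - onset and be non-negative")


def _canon_names(names: Iterable[str]) -> frozenset[str]:
    return frozenset(canonical(n) for n in names)


def select_cohort(
    orders: Sequence[MedicationOrder],
    drug_a_names: Iterable[str],
    drug_b_names: Iterable[str],
) -> CohortSelection:
    """Partition every patient appearing in ``orders`` by exclusive exposure."""
    a_names, b_names = _canon_names(drug_a_names), _canon_names(drug_b_names)
    if not a_names or not b_names:
        raise ValueError("drug name sets must be non-empty")
    overlap = a_names & b_names
    if overlap:
        raise ValueError(f"drug name sets overlap after canonicalization: {sorted(overlap)}")
    has_a: set[str] = set()
    has_b: set[str] = set()
    universe: set[str] = set()
    for o in orders:
        universe.add(o.patient_id)
        name = canonical(o.drug_name)
        if name in a_names:
            has_a.add(o.patient_id)
        elif name in b_names:
            has_b.add(o.patient_id)
    return CohortSelection(
        arm_a_patients=frozenset(has_a - has_b),
        arm_b_patients=frozenset(has_b - has_a),
        excluded_both=frozenset(has_a & has_b),
        excluded_neither=frozenset(universe - has_a - has_b),
    )


def first_dose_date(
    patient_id: str,
    orders: Sequence[MedicationOrder],
    drug_names: Iterable[str],
) -> datetime.date:
    """Earliest order date for this patient matching the given drug names."""
    names = _canon_names(drug_names)
    dates = [
        o.date
        for o in orders
        if o.patient_id == patient_id and canonical(o.drug_name) in names
    ]
    if not dates:
        raise ValueError(f"patient {patient_id!r} has no order matching the drug names")
    return min(dates)


def build_timeline(
    patient_id: str,
    events: Sequence[NormalizedEvent],
    target_term: str,
    first_dose: datetime.date,
    all_records: Sequence[DocumentRecord],
) -> PatientTimeline:
    """Anchor a patient's target-term events at first dose.

    Keeps events whose normalized term equals ``target_term``; duplicates on
    the same (day, doc_type) collapse to one.  Pre-dose events are dropped and
    counted in ``n_pre_dose_dropped``.  Follow-up ends at the patient's last
    record of any document type.
    """
    record_dates = [r.timestamp for r in all_records if r.patient_id == patient_id]
    if not record_dates:
        raise ValueError(f"patient {patient_id!r} has no records; cannot establish follow-up")
    followup_end = (max(record_dates) - first_dose).days

    kept: set[tuple[int, DocType]] = set()
    dropped = 0
    for e in events:
        if e.patient_id != patient_id or e.normalized != target_term:
            continue
        day = (e.date - first_dose).days
        if day < 0:
            dropped += 1
            continue
        kept.add((day, e.doc_type))
    if dropped:
        logger.info("patient %s: dropped %d pre-dose mention(s)", patient_id, dropped)
    return PatientTimeline(
        patient_id=patient_id,
        first_dose_date=first_dose,
        events=tuple(
            TimelineEvent(day, dt, target_term)
            for day, dt in sorted(kept, key=lambda t: (t[0], t[1].value))
        ),
        followup_end_day=max(followup_end, 0),
        n_pre_dose_dropped=dropped,
    )


def build_cohort_timelines(
    patient_ids: Iterable[str],
    events: Sequence[NormalizedEvent],
    target_term: str,
    orders: Sequence[MedicationOrder],
    drug_names: Iterable[str],
    all_records: Sequence[DocumentRecord],
) -> dict[str, PatientTimeline]:
    """Convenience wrapper: one timeline per included patient."""
    events_by_patient: dict[str, list[NormalizedEvent]] = {}
    for e in events:
        events_by_patient.setdefault(e.patient_id, []).append(e)
    records_by_patient: dict[str, list[DocumentRecord]] = {}
    for r in all_records:
        records_by_patient.setdefault(r.patient_id, []).append(r)
    out: dict[str, PatientTimeline] = {}
    for pid in patient_ids:
        first = first_dose_date(pid, orders, drug_names)
        out[pid] = build_timeline(
            pid,
            events_by_patient.get(pid, []),
            target_term,
            first,
            records_by_patient.get(pid, []),
        )
    return out


def onset_and_duration(timeline: PatientTimeline) -> OnsetSummary:
    """Onset = first event day, last = latest event day, duration = last − onset."""
    if not timeline.events:
        return OnsetSummary(onset_day=None, last_day=None, duration_days=None)
    days = [e.day_index for e in timeline.events]
    onset, last = min(days), max(days)
    return OnsetSummary(onset_day=onset, last_day=last, duration_days=last - onset)
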