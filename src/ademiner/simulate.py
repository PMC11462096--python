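"""Synthetic multitype clinical corpora with planted ground truth.

Real corpora of this kind are private hospital records, so every pipeline
stage is exercised against generated data instead.  The generator emulates the
*structure* of such data, not its language: per-patient medication orders of
two types, free-text records of six document types written on type-specific
encounter cadences (nurses chart often, radioisotope reports are rare), and
symptom mentions planted inside short Japanese sentence templates that
exercise the tagger's cue logic.

Each simulated patient has a latent disease course: an arm (drug A, drug B,
both, or neither), a first-dose date, a true adverse-event onset day drawn
from a Weibull distribution (or never), and a resolution day.  While the
patient is symptomatic, each document type records the symptom at its own
cadence with its own recording probability and charting delay — the
structural reason different document types show different detection rates
over time.  Planted mention classes mirror the failure modes seen in clinical
NER pipelines:

* affirmative — a dictionary surface form (or a close variant at known edit
  distance) in an affirmative sentence;
* negated — the symptom denied ("しびれなし");
* risk-explanation — side-effect counselling that names the symptom without
  the patient having it ("副作用として…のリスクについて説明"), an
  early-overdetection source for cue-blind taggers;
* onomatopoeic — a colloquial surface (びりびり) absent from the tagger
  lexicon, a structural false-negative.

The generator writes a :class:`GroundTruth` alongside the corpus: arm, first
dose, true onset/resolution, and every planted mention with its exact record
index and character span, so recovery can be checked mention-for-mention.
Identical seed and config give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import Corpus, DocType, DocumentRecord, MedicationOrder, OrderType
from .extract import Factuality
from .normalize import NormalizationDictionary, fixture_dictionary

__all__ = [
    "TemplateMix",
    "SimulationConfig",
    "PatientTruth",
    "PlantedMention",
    "GroundTruth",
    "simulate_corpus",
    "degrade",
    "DRUG_A_NAME",
    "DRUG_B_NAME",
    "TARGET_TERM",
]

DRUG_A_NAME = "パクリタキセル"  # paclitaxel
DRUG_B_NAME = "ドセタキセル"  # docetaxel
TARGET_TERM = "末梢神経障害"  # peripheral neuropathy, the target normalized term

_BASE_DATE = datetime.date(2020, 1, 15)

# Background line per document type: free of lexicon surfaces and of all
# negation/risk cues, so it never produces a mention.
_BACKGROUND = {
    DocType.physician_note: "経過観察。全身状態良好。",
    DocType.nursing_record: "バイタル測定。睡眠良好。",
    DocType.discharge_summary: "入院経過の要約。",
    DocType.radiology_report: "胸部CT撮影。",
    DocType.radioisotope_report: "骨シンチ撮影。",
    DocType.pharmacist_note: "服薬指導を実施。",
}

_AFFIRM_PREFIX, _AFFIRM_SUFFIX = "手足に", "あり。"
_NEGATED_SUFFIX = "なし。"
_RISK_PREFIX, _RISK_SUFFIX = "副作用として", "のリスクについて説明。"
_ONOMATOPOEIA_LINE, _ONOMATOPOEIA_SURFACE = "手足がびりびりする。", "びりびり"
_DISTRACTOR_PREFIX, _DISTRACTOR_SURFACE, _DISTRACTOR_SUFFIX = "下肢に", "浮腫", "あり。"

# PN surface forms planted in affirmative context, with sampling weights and
# an optional perturbed variant at known edit distance 1.
_PN_SURFACES = ("しびれ", "末梢神経障害", "感覚異常", "痛覚低下")
_PN_WEIGHTS = (0.6, 0.3, 0.05, 0.05)
_VARIANTS = {"しびれ": "しびれ感", "感覚異常": "感覚の異常"}


@dataclass(frozen=True)
class TemplateMix:
    """Relative weights of planted-mention classes.

    ``affirmative`` vs ``onomatopoeia`` are relative weights within each
    recorded symptomatic encounter; ``negated`` and ``risk`` are per-encounter
    probabilities of planting those classes on non-symptomatic records.
    """

    affirmative: float = 0.92
    negated: float = 0.08
    risk: float = 0.04
    onomatopoeia: float = 0.08

    def __post_init__(self) -> None:
        for name in ("affirmative", "negated", "risk", "onomatopoeia"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"template_mix.{name} must be in [0, 1], got {v}")
        if self.affirmative + self.onomatopoeia <= 0.0:
            raise ValueError("template_mix: affirmative + onomatopoeia must be positive")


def _default_cadence() -> dict[DocType, int]:
    return {
        DocType.physician_note: 7,
        DocType.nursing_record: 3,
        DocType.discharge_summary: 60,
        DocType.radiology_report: 90,
        DocType.radioisotope_report: 300,
        DocType.pharmacist_note: 21,
    }


def _default_recording_prob() -> dict[DocType, float]:
    return {
        DocType.physician_note: 0.5,
        DocType.nursing_record: 0.2,
        DocType.discharge_summary: 0.05,
        DocType.radiology_report: 0.01,
        DocType.radioisotope_report: 0.01,
        DocType.pharmacist_note: 0.6,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated corpus.

    Defaults emulate a breast-cancer taxane cohort: a small fraction of a
    large patient universe is exposed to exactly one of two taxanes; the
    adverse-event onset model is Weibull (shape 0.44, scale 27.6 days, 5.8%
    never developing), which puts the median onset among developers near 12
    days and the 30-day cumulative incidence near 61%; symptom-free duration
    ends after an exponential resolution time with median 92 days; follow-up
    is uniform between 90 and 1100 days.
    """

    n_patients: int = 300
    arm_fractions: tuple[float, float, float, float] = (0.045, 0.049, 0.0035, 0.9025)
    onset_shape: float = 0.44
    onset_scale_days: float = 27.6
    never_prob: float = 0.058
    duration_median_days: float = 92.0
    followup_range_days: tuple[int, int] = (90, 1100)
    cadence_days: dict[DocType, int] = field(default_factory=_default_cadence)
    recording_prob: dict[DocType, float] = field(default_factory=_default_recording_prob)
    delay_mean_days: float = 1.0
    template_mix: TemplateMix = field(default_factory=TemplateMix)
    variant_fraction: float = 0.1
    distractor_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if abs(sum(self.arm_fractions) - 1.0) > 1e-9 or any(
            not 0.0 <= f <= 1.0 for f in self.arm_fractions
        ):
            raise ValueError(f"arm_fractions must be in [0,1] and sum to 1: {self.arm_fractions}")
        for name in ("never_prob", "variant_fraction", "distractor_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.onset_shape <= 0 or self.onset_scale_days <= 0:
            raise ValueError("onset_shape and onset_scale_days must be positive")
        if self.duration_median_days <= 0:
            raise ValueError("duration_median_days must be positive")
        if self.delay_mean_days < 0:
            raise ValueError(f"delay_mean_days must be >= 0, got {self.delay_mean_days}")
        lo, hi = self.followup_range_days
        if not (0 < lo <= hi):
            raise ValueError(f"followup_range_days must satisfy 0 < lo <= hi: {self.followup_range_days}")
        for dt in DocType:
            if dt not in self.cadence_days or self.cadence_days[dt] < 1:
                raise ValueError(f"cadence_days[{dt.value}] must be a positive integer")
            if dt not in self.recording_prob or not (0.0 <= self.recording_prob[dt] <= 1.0):
                raise ValueError(f"recording_prob[{dt.value}] must be in [0, 1]")


@dataclass(frozen=True)
class PatientTruth:
    arm: str  # "A", "B", "both", "neither"
    first_dose_date: Optional[datetime.date]
    onset_day: Optional[int]
    resolution_day: Optional[int]
    followup_end_day: int


@dataclass(frozen=True)
class PlantedMention:
    """One planted mention with its exact location in the emitted corpus."""

    patient_id: str
    doc_type: DocType
    date: datetime.date
    record_index: int
    start: int
    end: int
    surface: str
    factuality: Factuality
    in_lexicon: bool  # False for onomatopoeic variants the tagger cannot see
    term: str  # the normalized term this mention stands for


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth]
    mentions: list[PlantedMention]
    dictionary: NormalizationDictionary
    tagger_lexicon: frozenset[str]

    def positive_pn_mentions(self) -> list[PlantedMention]:
        """Planted mentions the pipeline should recover as PN evidence."""
        return [
            m
            for m in self.mentions
            if m.factuality is Factuality.positive and m.in_lexicon and m.term == TARGET_TERM
        ]

    def true_onset_cdf(self, patient_ids, horizon: int) -> np.ndarray:
        """Empirical CDF of true onset day over the given patients, days 0..horizon."""
        ids = list(patient_ids)
        onsets = [self.patients[p].onset_day for p in ids]
        grid = np.arange(horizon + 1)
        counts = np.zeros(horizon + 1)
        for o in onsets:
            if o is not None and o <= horizon:
                counts[o] += 1
        return np.cumsum(counts) / len(ids)


class _RecordBuilder:
    """Accumulates lines per (patient, doc_type, date) and tracks mention spans."""

    def __init__(self) -> None:
        self._lines: dict[tuple[str, DocType, datetime.date], list[str]] = {}
        # pending mentions: (key, line_index, offset_in_line, surface, factuality, in_lexicon, term)
        self._pending: list[tuple] = []

    def add_line(self, pid: str, dt: DocType, date: datetime.date, line: str) -> None:
        self._lines.setdefault((pid, dt, date), []).append(line)

    def add_mention_line(
        self,
        pid: str,
        dt: DocType,
        date: datetime.date,
        prefix: str,
        surface: str,
        suffix: str,
        factuality: Factuality,
        in_lexicon: bool,
        term: str,
    ) -> None:
        key = (pid, dt, date)
        lines = self._lines.setdefault(key, [])
        self._pending.append(
            (key, len(lines), len(prefix), surface, factuality, in_lexicon, term)
        )
        lines.append(prefix + surface + suffix)

    def build(self) -> tuple[list[DocumentRecord], list[PlantedMention]]:
        records: list[DocumentRecord] = []
        index_of: dict[tuple[str, DocType, datetime.date], int] = {}
        for key in sorted(self._lines, key=lambda k: (k[0], k[2], k[1].value)):
            pid, dt, date = key
            index_of[key] = len(records)
            records.append(
                DocumentRecord(
                    patient_id=pid, doc_type=dt, timestamp=date,
                    text="\n".join(self._lines[key]),
                )
            )
        mentions: list[PlantedMention] = []
        for key, line_idx, in_line, surface, factuality, in_lexicon, term in self._pending:
            offset = sum(len(l) + 1 for l in self._lines[key][:line_idx]) + in_line
            pid, dt, date = key
            mentions.append(
                PlantedMention(
                    patient_id=pid, doc_type=dt, date=date,
                    record_index=index_of[key],
                    start=offset, end=offset + len(surface),
                    surface=surface, factuality=factuality,
                    in_lexicon=in_lexicon, term=term,
                )
            )
        mentions.sort(key=lambda m: (m.record_index, m.start))
        return records, mentions


def simulate_corpus(config: SimulationConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus ground truth; reproducible given the config seed."""
    rng = np.random.default_rng(config.seed)
    dictionary = fixture_dictionary()
    lexicon = frozenset(e.surface for e in dictionary.entries)
    duration_scale = config.duration_median_days / np.log(2.0)
    mix = config.template_mix
    p_onomatopoeia = mix.onomatopoeia / (mix.affirmative + mix.onomatopoeia)

    builder = _RecordBuilder()
    orders: list[MedicationOrder] = []
    patients: dict[str, PatientTruth] = {}

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        arm = ("A", "B", "both", "neither")[
            int(rng.choice(4, p=np.asarray(config.arm_fractions)))
        ]
        index_date = _BASE_DATE + datetime.timedelta(days=int(rng.integers(0, 61)))
        followup_end = int(rng.integers(config.followup_range_days[0],
                                        config.followup_range_days[1] + 1))

        # Orders: weekly drug-A cycles, tri-weekly drug-B cycles, and one
        # supportive medicine order so every patient appears in the orders file.
        if arm in ("A", "both"):
            for c in range(12):
                orders.append(MedicationOrder(pid, OrderType.injection, DRUG_A_NAME,
                                              index_date + datetime.timedelta(days=7 * c)))
        if arm in ("B", "both"):
            b_start = 84 if arm == "both" else 0
            for c in range(4):
                orders.append(MedicationOrder(pid, OrderType.injection, DRUG_B_NAME,
                                              index_date + datetime.timedelta(days=b_start + 21 * c)))
        orders.append(MedicationOrder(pid, OrderType.medicine, "ロキソプロフェン", index_date))

        # Latent disease course (taxane-exposed patients only).
        onset: Optional[int] = None
        resolution: Optional[int] = None
        if arm in ("A", "B", "both") and rng.random() >= config.never_prob:
            onset = max(1, int(np.ceil(config.onset_scale_days * rng.weibull(config.onset_shape))))
            resolution = onset + int(np.ceil(rng.exponential(duration_scale)))
        patients[pid] = PatientTruth(arm, index_date if arm != "neither" else None,
                                     onset, resolution, followup_end)

        symptomatic_end = min(resolution, followup_end) if onset is not None else -1
        for dt in DocType:
            cadence = config.cadence_days[dt]
            background_days = set(range(0, followup_end + 1, cadence))
            symptomatic_days: set[int] = set()
            if onset is not None and onset <= symptomatic_end:
                symptomatic_days = set(range(onset, symptomatic_end + 1, cadence))

            for day in sorted(background_days | symptomatic_days):
                date = index_date + datetime.timedelta(days=day)
                if day in symptomatic_days:
                    if rng.random() < config.recording_prob[dt]:
                        delay = int(rng.poisson(config.delay_mean_days)) \
                            if config.delay_mean_days > 0 else 0
                        mdate = index_date + datetime.timedelta(days=day + delay)
                        if rng.random() < p_onomatopoeia:
                            off = _ONOMATOPOEIA_LINE.index(_ONOMATOPOEIA_SURFACE)
                            builder.add_mention_line(
                                pid, dt, mdate,
                                _ONOMATOPOEIA_LINE[:off], _ONOMATOPOEIA_SURFACE,
                                _ONOMATOPOEIA_LINE[off + len(_ONOMATOPOEIA_SURFACE):],
                                Factuality.positive, in_lexicon=False, term=TARGET_TERM,
                            )
                        else:
                            surface = str(rng.choice(_PN_SURFACES, p=np.asarray(_PN_WEIGHTS)))
                            if surface in _VARIANTS and rng.random() < config.variant_fraction:
                                surface = _VARIANTS[surface]
                            builder.add_mention_line(
                                pid, dt, mdate, _AFFIRM_PREFIX, surface, _AFFIRM_SUFFIX,
                                Factuality.positive, in_lexicon=True, term=TARGET_TERM,
                            )
                    elif day in background_days:
                        builder.add_line(pid, dt, date, _BACKGROUND[dt])
                else:
                    # Non-symptomatic encounter: background text, possibly a
                    # negated / risk-explanation / distractor mention.
                    builder.add_line(pid, dt, date, _BACKGROUND[dt])
                    u = rng.random()
                    if u < mix.negated:
                        builder.add_mention_line(
                            pid, dt, date, "", "しびれ", _NEGATED_SUFFIX,
                            Factuality.negative, in_lexicon=True, term=TARGET_TERM,
                        )
                    elif u < mix.negated + mix.risk:
                        builder.add_mention_line(
                            pid, dt, date, _RISK_PREFIX, TARGET_TERM, _RISK_SUFFIX,
                            Factuality.suspected, in_lexicon=True, term=TARGET_TERM,
                        )
                    elif u < mix.negated + mix.risk + config.distractor_prob:
                        builder.add_mention_line(
                            pid, dt, date, _DISTRACTOR_PREFIX, _DISTRACTOR_SURFACE,
                            _DISTRACTOR_SUFFIX,
                            Factuality.positive, in_lexicon=True, term=_DISTRACTOR_SURFACE,
                        )

    records, mentions = builder.build()
    corpus = Corpus(records=records, orders=sorted(
        orders, key=lambda o: (o.patient_id, o.date, o.order_type.value, o.drug_name)
    ))
    truth = GroundTruth(
        patients=patients, mentions=mentions,
        dictionary=dictionary, tagger_lexicon=lexicon,
    )
    return corpus, truth


def degrade(config: SimulationConfig, **knobs) -> SimulationConfig:
    """Return a config with specified miss / false-positive rates injected.

    Recognized knobs: ``onomatopoeia``, ``risk``, ``negated`` (template-mix
    fractions), plus any :class:`SimulationConfig` field name.  With no knobs
    this is the identity.
    """
    mix_fields = {k: knobs.pop(k) for k in ("onomatopoeia", "risk", "negated", "affirmative")
                  if k in knobs}
    unknown = set(knobs) - {f.name for f in dataclasses.fields(SimulationConfig)}
    if unknown:
        raise ValueError(f"unknown degradation knob(s): {sorted(unknown)}")
    if mix_fields:
        knobs["template_mix"] = dataclasses.replace(config.template_mix, **mix_fields)
    return dataclasses.replace(config, **knobs) if knobs else config
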