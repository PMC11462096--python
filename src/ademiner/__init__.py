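"""ademiner: adverse-drug-event detection from multitype clinical documents.

The pipeline has four stages, each usable on its own:

1. :mod:`ademiner.extract` — symptom-mention extraction with factuality
   labels (built-in lexicon/rule tagger, or an adapter for external NER
   output); only positive-factuality mentions proceed.
2. :mod:`ademiner.normalize` — minimum-Levenshtein-distance mapping of
   surface forms onto normalized symptom terms.
3. :mod:`ademiner.timeline` — exclusive-exposure cohort selection and
   first-dose-anchored per-patient timelines (onset, last detection,
   duration).
4. :mod:`ademiner.incidence` — Kaplan-Meier cumulative incidence with 95%
   bands, per-document-type curves, and curve-comparison statistics
   (detection gap/ratio, Pearson correlation, OLS decomposition).

:mod:`ademiner.simulate` generates synthetic corpora with planted ground
truth so the whole chain is testable without access to hospital data.
"""

from __future__ import annotations

from typing import Optional

from . import corpus, extract, incidence, normalize, simulate, timeline
from .corpus import Corpus
from .extract import TaggerConfig, filter_positive, tag_corpus
from .normalize import NormalizationDictionary, normalize_all
from .timeline import PatientTimeline, build_cohort_timelines, select_cohort

__version__ = "0.1.0"

__all__ = [
    "corpus",
    "extract",
    "normalize",
    "timeline",
    "incidence",
    "simulate",
    "run_pipeline",
    "__version__",
]


def run_pipeline(
    corpus_obj: Corpus,
    dictionary: NormalizationDictionary,
    target_term: str,
    drug_a_names: set[str],
    drug_b_names: set[str],
    tagger_config: Optional[TaggerConfig] = None,
    max_distance: Optional[int] = None,
) -> tuple[dict[str, PatientTimeline], dict[str, PatientTimeline]]:
    """Run extraction → factuality filter → normalization → timelines.

    Returns ``(arm_a_timelines, arm_b_timelines)`` keyed by patient id.
    Patients exposed to both drugs or to neither are excluded by
    :func:`ademiner.timeline.select_cohort`.  The default tagger lexicon is
    the dictionary's surface forms.
    """
    if tagger_config is None:
        tagger_config = TaggerConfig(lexicon=frozenset(dictionary.surfaces))
    selection = select_cohort(corpus_obj.orders, drug_a_names, drug_b_names)
    mentions = tag_corpus(corpus_obj, tagger_config, patient_ids=set(selection.included))
    events = normalize_all(filter_positive(mentions), dictionary, max_distance=max_distance)
    arm_a = build_cohort_timelines(
        sorted(selection.arm_a_patients), events, target_term,
        corpus_obj.orders, drug_a_names, corpus_obj.records,
    )
    arm_b = build_cohort_timelines(
        sorted(selection.arm_b_patients), events, target_term,
        corpus_obj.orders, drug_b_names, corpus_obj.records,
    )
    return arm_a, arm_b
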