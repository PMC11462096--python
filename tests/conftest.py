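import datetime

import pytest

from ademiner.corpus import Corpus, DocType, DocumentRecord, MedicationOrder, OrderType
from ademiner.normalize import fixture_dictionary
from ademiner.simulate import SimulationConfig, TemplateMix


@pytest.fixture(scope="session")
def dictionary():
    return fixture_dictionary()


@pytest.fixture
def small_corpus():
    d = datetime.date
    records = [
        DocumentRecord("p1", DocType.physician_note, d(2020, 3, 15), "手足のしびれあり"),
        DocumentRecord("p1", DocType.pharmacist_note, d(2020, 4, 2), "経過順調。\nしびれなし。"),
        DocumentRecord("p2", DocType.nursing_record, d(2020, 3, 20), "タブ\tと\"引用\"を含む\n複数行テキスト"),
    ]
    orders = [
        MedicationOrder("p1", OrderType.injection, "パクリタキセル", d(2020, 3, 10)),
        MedicationOrder("p2", OrderType.medicine, "ロキソプロフェン", d(2020, 3, 1)),
    ]
    return Corpus(records=records, orders=orders)


def clean_config(**overrides) -> SimulationConfig:
    """A zero-noise simulation: every doc type records every symptomatic
    encounter with no delay, all mentions affirmative with exact dictionary
    surfaces.  Under these conditions the pipeline must recover ground truth
    exactly."""
    base = dict(
        arm_fractions=(0.5, 0.5, 0.0, 0.0),
        recording_prob={dt: 1.0 for dt in DocType},
        delay_mean_days=0.0,
        template_mix=TemplateMix(affirmative=1.0, negated=0.0, risk=0.0, onomatopoeia=0.0),
        variant_fraction=0.0,
        distractor_prob=0.0,
        followup_range_days=(120, 250),
    )
    base.update(overrides)
    return SimulationConfig(**base)
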