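from datetime import datetime, timedelta

import numpy as np
import pytest

from capscreen.encoders import RuleLexicon
from capscreen.preprocess import CleanCorpus, PatientRecord, RawNote
from capscreen.synthetic import CohortConfig, generate_cohort, generate_lexicon

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def make_record(patient_id, label, role_texts, start=None):
    """Build a PatientRecord from (role, text) pairs with hourly timestamps."""
    start = start or datetime(2016, 1, 1)
    notes = [
        RawNote(role, start + timedelta(hours=i), text)
        for i, (role, text) in enumerate(role_texts)
    ]
    return PatientRecord(patient_id, label, notes)


@pytest.fixture
def tiny_corpora():
    """Three hand-countable corpora used for TF-IDF fixtures."""
    return [
        CleanCorpus("p1", ["rib", "fracture", "rib"]),
        CleanCorpus("p2", ["bruise", "fracture"]),
        CleanCorpus("p3", ["bruise", "swelling"]),
    ]


@pytest.fixture
def clinical_lexicon():
    """A small realistic-phrase lexicon, cleaned as the corpora are."""
    return RuleLexicon.from_raw(
        ["rib fracture", "consistent mechanism", "retinal hemorrhage"],
        ["positive", "negative", "positive"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A quick strongly-signalled single-phrase cohort plus its config."""
    lexicon = generate_lexicon(1, 0, seed=3)
    config = CohortConfig(
        n_patients=80,
        lexicon=lexicon,
        prevalence=0.5,
        p_present_pos=[0.9],
        p_present_neg=[0.1],
        notes_per_patient=(2, 0.4),
        words_per_note=(40.0, 0.6),
        background_vocab_size=300,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
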