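"""Shared fixtures: one small preprocessed cohort reused across test modules."""

import numpy as np
import pytest

from tffo import CohortSpec, bandpass_normalize, epoch_and_exclude, generate_cohort

SMALL_LABELS = ("F2", "FC3", "Pz")


def preprocess_cohort(recordings):
    """Band-pass + normalize + epoch every recording; returns (sets, labels)."""
    sets, labels = [], {}
    for rec in recordings:
        sets.append(epoch_and_exclude(bandpass_normalize(rec)))
        labels[rec.subject_id] = rec.group
    return sets, labels


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 subjects, 3 EEG channels, clear effect at [200,300] ms × [15,20] Hz."""
    spec = CohortSpec(
        n_per_group=8,
        channel_labels=SMALL_LABELS,
        effect_windows=((200.0, 300.0),),
        effect_size=0.3,
        seed=1234,
    )
    return preprocess_cohort(generate_cohort(spec))


@pytest.fixture(scope="session")
def null_cohort():
    """6+6 subjects with no injected group difference (effect_size = 1)."""
    spec = CohortSpec(
        n_per_group=6,
        channel_labels=SMALL_LABELS,
        effect_windows=((200.0, 300.0),),
        effect_size=1.0,
        seed=4321,
    )
    return preprocess_cohort(generate_cohort(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
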