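import numpy as np
import pytest

from escnn import CohortSpec, synth_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects (2 spectral groups) x 60 epochs at 100 Hz."""
    spec = CohortSpec(n_subjects_per_group=2, n_groups=2,
                      epochs_per_subject=60, fs=100.0, seed=11)
    return synth_cohort(spec)


@pytest.fixture(scope="session")
def one_night(tiny_cohort):
    recs, _ = tiny_cohort
    return recs[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
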