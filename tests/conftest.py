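import numpy as np
import pytest

from gaitid.cycles import extract_cycles
from gaitid.features import feature_table
from gaitid.synthetic import CohortSpec, WalkerParams, generate_cohort, generate_walk


@pytest.fixture(scope="session")
def default_walk():
    """One noise-free walker bout of 8 full cycles at 25 fps, with ground truth."""
    seq, events = generate_walk(WalkerParams(seed=1), n_strides=8, fps=25.0)
    return seq, events


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free 20-subject cohort, 12 cycles each, 25 fps (with ground truth)."""
    return generate_cohort(CohortSpec(n_subjects=20, cycles_per_subject=12, fps=25.0, seed=5))


@pytest.fixture(scope="session")
def clean_cycles(clean_cohort):
    seqs, _ = clean_cohort
    return [(s.subject_id, extract_cycles(s)) for s in seqs]


@pytest.fixture(scope="session")
def clean_table(clean_cycles):
    return feature_table(clean_cycles)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
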