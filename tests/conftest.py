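"""Shared fixtures: small deterministic cohorts reused across test modules."""

import pytest

from pavcal.design import DesignSpec, generate_trial_sequence
from pavcal.synthetic import CohortSpec, noiseless, simulate_cohort


@pytest.fixture(scope="session")
def learning_events():
    """One deterministic learning-phase event table."""
    return generate_trial_sequence(DesignSpec(), phase="learning", seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Two noiseless participants with delta=0.6 (recovery oracles)."""
    spec = noiseless(CohortSpec(n_participants=2, delta=0.6, seed=7))
    return simulate_cohort(DesignSpec(), spec)


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_cohort):
    return noiseless_cohort[0]


@pytest.fixture(scope="session")
def noisy_cohort():
    """Two participants at default (study-condition) noise levels."""
    return simulate_cohort(DesignSpec(), CohortSpec(n_participants=2, seed=3))
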