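import dataclasses

import numpy as np
import pytest

from erpbci.cohort import (
    AMPLITUDE_SCALE_MEAN,
    COMPONENTS,
    LATENCY_MEAN,
    TOPOGRAPHIES,
    SpellerSpec,
    VirtualParticipant,
    make_cohort,
)


@pytest.fixture(scope="session")
def mean_participant() -> VirtualParticipant:
    """Noiseless participant at the exact calibration means."""
    return VirtualParticipant(
        id="MEAN", aptitude=0.8,
        comp_amp={c: AMPLITUDE_SCALE_MEAN[c] * TOPOGRAPHIES[c]
                  for c in COMPONENTS},
        comp_lat=dict(LATENCY_MEAN),
        noise_sd=0.0, blink_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(8, planted_rho=-0.85, seed=11)


@pytest.fixture(scope="session")
def noisy_participant(small_cohort) -> VirtualParticipant:
    return small_cohort[0]


@pytest.fixture(scope="session")
def quiet_participant(small_cohort) -> VirtualParticipant:
    """Cohort participant with noise and blinks switched off."""
    return dataclasses.replace(small_cohort[1], noise_sd=0.0, blink_rate=0.0)


@pytest.fixture
def small_speller_specs():
    """Problem sizes small enough for the unit-test budget."""
    train = SpellerSpec(n_selections=6, repetitions_per_selection=4,
                        pause_after_selection_s=1.5)
    test = SpellerSpec(n_selections=8, repetitions_per_selection=3,
                       pause_after_selection_s=1.5)
    return train, test


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230918)
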