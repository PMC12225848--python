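import numpy as np
import pytest

from wmdecode import CohortSpec, PlantedCoupling, generate_cohort


def tiny_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Smallest valid cohort: one channel per region, short trials."""
    kwargs = dict(
        n_subjects=1,
        channels_per_region={"MTL": 1, "PFC": 1, "OFC": 1},
        trials_per_condition=10,
        trial_count_jitter=0,
        sampling_rate=250.0,
        window_length=0.6,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def theta_coupled_spec(seed: int = 0, gain: float = 0.6, **overrides) -> CohortSpec:
    """Tiny cohort with one known MTL->PFC coupling active only in the
    spatial condition; the source's 6 Hz core makes the effect theta-band."""
    return tiny_spec(
        seed=seed,
        coupling_edges=[
            PlantedCoupling(0, 1, lag=1, gain=gain, conditions=("spatial",))
        ],
        **overrides,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    trials, ground_truth = generate_cohort(tiny_spec(seed=11))
    return trials, ground_truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
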