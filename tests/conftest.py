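import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-signal cohort shared by read-only tests."""
    from msmilestone import SignalSpec, generate_cohort

    spec = SignalSpec(
        n_patients=40, prevalence=0.3, lab_shift=1.5,
        lesion_count_pos=4.0, lesion_count_neg=1.0,
        note_signal_tokens={"relapse": 4.0},
        sequences=("flair",), volume_shape=(16, 16, 16),
        note_length=40, seed=77,
    )
    return generate_cohort(spec)
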