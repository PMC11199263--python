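import numpy as np
import pytest

from mstates.montage import spherical_cap_montage
from mstates.recording import Recording, average_reference
from mstates.synth import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def montage16():
    return spherical_cap_montage(16)


@pytest.fixture(scope="session")
def montage105():
    return spherical_cap_montage(105)


@pytest.fixture()
def random_recording(montage16):
    rng = np.random.default_rng(7)
    rec = Recording(
        data=rng.standard_normal((16, 500)), srate=250.0, montage=montage16
    )
    return average_reference(rec)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 1 minute, default SNR — shared across slow-ish tests."""
    spec = SyntheticSpec(n_subjects=3, minutes=1.0, seed=11)
    return generate_cohort(spec)
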