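import numpy as np
import pytest

from sanityscan import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec():
    """Small phantom geometry for fast unit tests."""
    return PhantomSpec(
        grid=(8, 64, 64),
        spacing=(1.25, 1.0, 1.0),
        organ_center=(32.0, 32.0),
        organ_radii=(17.0, 13.0),
        lesion_radius=5.0,
        center_jitter=(3.0, 3.0),
        clutter_radius=(4.0, 9.0),
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    """10-patient balanced cohort of small phantoms."""
    return generate_cohort(tiny_spec, n_per_class=5, seed=7).items


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
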