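import numpy as np
import pytest

from mandiblo.synthetic import CohortSpec, make_cohort, make_template


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects with all effects on, annotation noise included."""
    return make_cohort(CohortSpec(n=30, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: contours depend on age/sex/jitter only."""
    spec = CohortSpec(n=40, seed=5, noise_sd=0.0)
    return make_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
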