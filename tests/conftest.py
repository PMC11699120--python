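import numpy as np
import pytest

from condylokit.simulate import CohortConfig, generate_cohort
from condylokit.template import make_template_mandible


@pytest.fixture(scope="session")
def template():
    return make_template_mandible(2000)


@pytest.fixture(scope="session")
def small_cohort():
    """Mesh-bearing cohort, enriched prevalence so both classes appear."""
    return generate_cohort(CohortConfig(n_patients=12, seed=3, resorption_prevalence=0.4))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
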