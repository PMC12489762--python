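import numpy as np
import pytest

import parkdx as px


@pytest.fixture(scope="session")
def published_spec():
    """The published study conditions: 38/25/10 patients, printed marginals."""
    return px.published_cohort_spec()


@pytest.fixture(scope="session")
def cohort73(published_spec):
    """One synthetic 73-patient cohort drawn from the published distributions."""
    return px.simulate_cohort(published_spec, seed=20260921)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
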