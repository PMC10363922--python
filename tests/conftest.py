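import numpy as np
import pytest

import speccurve as sc


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (88 healthy + 117 stroke) with latent structure."""
    return sc.generate_cohort(sc.CohortParams(seed=0))


@pytest.fixture(scope="session")
def full_specs():
    return sc.enumerate_specs()


@pytest.fixture(scope="session")
def full_mv(default_cohort, full_specs):
    """The full 2,220-spec multiverse on the default cohort."""
    return sc.run_multiverse(default_cohort, full_specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
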