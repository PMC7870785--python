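import numpy as np
import pytest

from serumscreen import (
    MedianNormalizer,
    default_config,
    generate_cohort,
    load_default_params,
)


@pytest.fixture(scope="session")
def table_params():
    """Packaged reference-population Gaussian parameters per group."""
    return load_default_params()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced simulated cohort (fast) with all three groups."""
    config = default_config(seed=42)
    config.group_sizes = {"control": 300, "T21": 60, "T18": 40}
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_mom(small_cohort):
    normalizer = MedianNormalizer().fit(small_cohort)
    return normalizer.transform(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
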