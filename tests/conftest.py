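import numpy as np
import pytest

from dynsig import CohortSpec, generate_cohort, generate_null_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 4 regions, strong SD effect in region 0."""
    spec = CohortSpec(
        n_per_group=(10, 10), n_regions=4, n_timepoints=120, seed=7,
        sd_scale=((0,), 1.5),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    spec = CohortSpec(n_per_group=(10, 10), n_regions=4, n_timepoints=120, seed=3)
    return generate_null_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from dynsig import compute_feature_tensor

    return compute_feature_tensor(small_cohort)
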