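import numpy as np
import pytest

from wmperf.synthetic import CohortConfig, make_phantom_anatomy


@pytest.fixture(scope="session")
def anatomy():
    """Shared small phantom: 32x32x16 at 2 mm, 2 slabs + 2 tubes."""
    return make_phantom_anatomy((32, 32, 16), (2.0, 2.0, 2.0), n_tracts=4, seed=1)


@pytest.fixture()
def quiet_cohort():
    """Noise-free cohort configuration for exactness tests."""
    return CohortConfig(
        n_subjects=4,
        coupled_tracts=(1, 2),
        null_tracts=(3, 4),
        noise_sd_asl=0.0,
        cbf_texture_sd=0.0,
        dti_texture_sd=0.0,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
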