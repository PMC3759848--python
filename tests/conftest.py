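import numpy as np
import pytest

from strokemap import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=7, n_sham=10, n_striatal=10, n_striatal_cortical=10)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """Full phantom cohort (images, fields, Jacobians), n = 30."""
    return generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def masks_only_cohort():
    """Lesions and behaviour only; cheap enough for repeated analyses."""
    cfg = SyntheticConfig(
        seed=11, n_sham=10, n_striatal=10, n_striatal_cortical=10,
        make_fields=False, make_images=False,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
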