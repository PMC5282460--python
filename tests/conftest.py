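import numpy as np
import pytest

from celltex3d import generate_cohort
from celltex3d.pipeline import extract_features, validate_config

# Reduced-size cohort shared by feature/selection/classification tests: same
# class structure as the default conditions (27 samples, 16 bands) at a
# smaller spatial size so the whole suite stays fast.
COHORT_KW = dict(image_size=96, n_bands=16)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(9, base_seed=1, **COHORT_KW)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    cfg = validate_config(dict(COHORT_KW))
    return extract_features(small_cohort, [s.truth_mask for s in small_cohort], cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
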