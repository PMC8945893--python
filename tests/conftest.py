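import numpy as np
import pytest

import habitatmri as hm


@pytest.fixture(scope="session")
def phantom_cohort():
    """Small separable phantom cohort (48^3 grid) shared across tests."""
    geo = hm.HabitatGeometryConfig(grid_shape=(48, 48, 48), shape_perturbation=0.1)
    subjects, log = hm.generate_cohort(
        hm.local_cohort_preset(), geometry=geo, seed=0, n_subjects=12
    )
    return subjects, log


@pytest.fixture(scope="session")
def fitted_extractor(phantom_cohort):
    subjects, _ = phantom_cohort
    return hm.RegionFeatureExtractor(n_words=256, random_state=0).fit(subjects)


@pytest.fixture(scope="session")
def feature_table(phantom_cohort, fitted_extractor):
    subjects, _ = phantom_cohort
    return fitted_extractor.transform(subjects)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
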