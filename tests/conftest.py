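import numpy as np
import pytest

from olfcluster.cohort import generate_cohort, scaled_config
from olfcluster.io import records_to_frame
from olfcluster.mixture import MixtureFeaturizer
from olfcluster.preprocess import age_sex_correct


@pytest.fixture(scope="session")
def small_cohort():
    """1,000-subject synthetic cohort (default profiles, seed 11)."""
    return records_to_frame(generate_cohort(scaled_config(1000, seed=11)))


@pytest.fixture(scope="session")
def corrected_cohort(small_cohort):
    frame, _ = age_sex_correct(small_cohort)
    return frame


@pytest.fixture(scope="session")
def features(corrected_cohort):
    """n x 9 posterior feature matrix of the small cohort."""
    featurizer = MixtureFeaturizer(random_state=11)
    return featurizer.fit(corrected_cohort).transform(corrected_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
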