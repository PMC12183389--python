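import warnings

import numpy as np
import pytest

from evsig.core_io import FourClassLabel, derive_labels
from evsig.preprocess import filter_group_presence, filter_min_individuals, impute_for_ml
from evsig.synthetic import SyntheticConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", module="lifelines")

SMALL_COUNTS = {
    FourClassLabel.NORMAL: 12,
    FourClassLabel.OTHER_SUBTYPE: 20,
    FourClassLabel.TNBC_NO_RECUR: 10,
    FourClassLabel.TNBC_RECUR: 8,
}


def small_config(**overrides) -> SyntheticConfig:
    """A reduced cohort (60 proteins x 50 samples) for fast unit tests."""
    kw = dict(n_proteins=60, n_per_class=dict(SMALL_COUNTS), seed=11)
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    matrix, annotations = generate_cohort(small_config())
    return matrix, annotations


@pytest.fixture(scope="session")
def small_imputed(small_cohort):
    matrix, annotations = small_cohort
    m1, _ = filter_min_individuals(matrix, annotations, min_n=5)
    m2, _ = filter_group_presence(m1, annotations, min_fraction=0.5)
    return impute_for_ml(m2), annotations, derive_labels(annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
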