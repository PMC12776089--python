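import warnings

import numpy as np
import pytest

from tausynth.atlas import build_atlas
from tausynth.phantom import PhantomParams, simulate_cohort
from tausynth import tabular as tb

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def atlas16():
    return build_atlas((16, 16, 16), 8, seed=1)


@pytest.fixture(scope="session")
def atlas12():
    return build_atlas((12, 12, 12), 8, seed=1)


@pytest.fixture(scope="session")
def cohort60(atlas12):
    """Baseline-visit phantom cohort used by several modules."""
    return simulate_cohort(atlas12, PhantomParams(), 60, seed=42)


@pytest.fixture(scope="session")
def aux_models(atlas12, cohort60):
    return tb.fit_auxiliary(tb.cohort_feature_table(cohort60),
                            tb.cohort_targets(cohort60, atlas12),
                            atlas12.roi_ids, atlas=atlas12, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
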