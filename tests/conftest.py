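import logging

import numpy as np
import pytest

from semdwi import BValueScheme, make_biopsy_targets, make_phantom

# the ROI-area tolerance warning fires on every default-grid placement;
# keep test output readable
logging.getLogger("semdwi.roi_extraction").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme.default()


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 24x24x6 phantom shared across tests."""
    return make_phantom((24, 24, 6), seed=11)


@pytest.fixture(scope="session")
def cohort_inputs():
    """A phantom plus 32 biopsy targets for cohort-level tests."""
    truth, dwi = make_phantom((48, 48, 8), seed=3)
    targets = make_biopsy_targets(truth, n_targets=32, n_patients=21, seed=3)
    return truth, dwi, targets


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
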