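import numpy as np
import pytest

from embryocal.benchmarks import (
    detector_cross_validation,
    detector_oracle_equivalence,
)
from embryocal.synthdata import SimConfig, calibrate_kernel, make_embryo_layout


@pytest.fixture(scope="session")
def kernel():
    """Default transient kernel (amplitude 100 AU, FWHM 20 s)."""
    return calibrate_kernel(100.0, 20.0, 5.0)


@pytest.fixture(scope="session")
def small_layout():
    return make_embryo_layout(
        {"epiblast": 4, "ExE": 4, "emVE": 3, "exVE": 3}, seed=0
    )


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def detector_recovery():
    """Truth-labeled CNN benchmark at SNR 5 (shared: training is the
    expensive part; several tests interrogate the same fitted model)."""
    return detector_cross_validation(seed=0)


@pytest.fixture(scope="session")
def oracle_equivalence():
    """Oracle-labeled CNN agreement benchmark at SNR 5."""
    return detector_oracle_equivalence(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
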