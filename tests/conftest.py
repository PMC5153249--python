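import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from picshift import EquilibriumConstants, MixtureTotals

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# lmfit emits covariance warnings on exactly-fitting noiseless curves
warnings.filterwarnings("ignore", category=RuntimeWarning, module="lmfit")


@pytest.fixture(scope="session")
def wt_constants() -> EquilibriumConstants:
    """Wild-type-like cycle: TC:43S 104 nM, eIF3:PIC 38 nM, TC:40S-eIF3 15 nM."""
    return EquilibriumConstants.from_cycle(104.0, 38.0, 15.0)


@pytest.fixture(scope="session")
def assay_totals() -> MixtureTotals:
    """eIF3-titration mixture: 30 nM 40S, 2 nM tracer TC (eIF3 varies per lane)."""
    return MixtureTotals(30.0, 2.0, 0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
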