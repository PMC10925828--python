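import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellcompete import CompetitionSystem, GridSpec, LogisticParams

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: The headline parameter estimates of the assay (medians across replicates):
#: DFT1 r=0.40/day, K=8.15e5 cells; DFT2 r=0.76/day, K=4.2e5 cells;
#: competition coefficients alpha=78 (DFT2 on DFT1), beta=15 (DFT1 on DFT2).
PAPER_SYSTEM = CompetitionSystem(r1=0.40, r2=0.76, K1=8.15e5, K2=4.2e5,
                                 alpha=78.0, beta=15.0)


@pytest.fixture
def paper_system() -> CompetitionSystem:
    return PAPER_SYSTEM


@pytest.fixture
def assay_days() -> np.ndarray:
    """Daily sampling days of the 14-day direct-culture assay."""
    return np.arange(1, 15, dtype=float)


@pytest.fixture
def dft1_params() -> LogisticParams:
    return LogisticParams(r=0.40, K=8.2e5)


@pytest.fixture
def dft2_params() -> LogisticParams:
    return LogisticParams(r=0.76, K=4.2e5)


@pytest.fixture
def coarse_lv_grid() -> GridSpec:
    """Small (alpha, beta) grid containing the headline (78, 15) point."""
    return GridSpec(alpha_min=0.0, alpha_max=99.0, alpha_step=3.0,
                    beta_min=0.0, beta_max=99.0, beta_step=3.0)
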