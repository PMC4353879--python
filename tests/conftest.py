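import numpy as np
import pytest

from mdfret import PhotophysicsParams


@pytest.fixture
def wt_params() -> PhotophysicsParams:
    """Wild-type donor photophysics: tau_d = 2.57 ns, R_F = 24 Å."""
    return PhotophysicsParams(tau_d=2.57, r_forster=24.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150310)
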