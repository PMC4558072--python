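import warnings

import numpy as np
import pytest

from snsurv.distributions import GompertzParams, SkewNormalCP, cp_to_dp, sn_rvs
from snsurv.lifetable import build_lifetable, gompertz_makeham_rates, lifetable_to_individuals

# the study conditions: parameters obtained by fitting both laws to adult
# mortality (used throughout the simulation-facing tests)
SN_CP = SkewNormalCP(mu=82.1, s=11.1, gamma1=-0.836)
GOMP = GompertzParams(alpha=float(np.exp(-12.25)), gamma=0.116)


@pytest.fixture(scope="session")
def sn_cp():
    return SN_CP


@pytest.fixture(scope="session")
def sn_dp():
    return cp_to_dp(SN_CP)


@pytest.fixture(scope="session")
def gomp():
    return GOMP


@pytest.fixture(scope="session")
def sn_sample_10k(sn_dp):
    return sn_rvs(sn_dp, 10_000, np.random.default_rng(20260101))


@pytest.fixture(scope="session")
def makeham_individuals():
    """Ages at death of a 100,000-person hypothetical population built from
    a synthetic Gompertz-Makeham rate table (no real national rates)."""
    lt = build_lifetable(gompertz_makeham_rates(), N=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lifetable_to_individuals(lt, random_state=7)
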