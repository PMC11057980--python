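import numpy as np
import pytest

from balancesrm import (
    ComKinematics,
    FeedbackGains,
    LoopTiming,
    SRMParams,
    SRMSpec,
    TimeSeries,
    make_com,
)


@pytest.fixture(scope="session")
def small_com() -> ComKinematics:
    """CoM balance-error response to the small perturbation (shared; read-only)."""
    return make_com("small")


@pytest.fixture(scope="session")
def msrm_truth() -> SRMParams:
    return SRMParams(
        SRMSpec.for_variant("mSRM"),
        FeedbackGains(k_d=0.03, k_v=0.01, k_a=0.002),
        LoopTiming(lambda_bs=105.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_com(rng: np.random.Generator, n: int = 20, fs: float = 1000.0) -> ComKinematics:
    """Small random kinematic triplet for oracle comparisons."""
    t0 = -5.0
    mk = lambda: TimeSeries(rng.normal(0.0, 1.0, n), fs, t0)
    return ComKinematics(mk(), mk(), mk())
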