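import numpy as np
import pytest

from dpgbcox.data import SurvivalDataset


@pytest.fixture
def tiny_dataset() -> SurvivalDataset:
    """3 subjects, one z and one v column, last subject censored."""
    return SurvivalDataset(
        time=np.array([1.0, 2.0, 3.0]),
        event=np.array([1.0, 1.0, 0.0]),
        exposure=np.array([0.1, 0.2, 0.3]),
        z=np.array([0.5, 1.0, 1.5]),
        v=np.array([0.0, 1.0, 0.0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_survival(rng, n=20, p_z=1, p_v=1, censor=0.2):
    """Small random dataset for property checks."""
    time = rng.exponential(1.0, n) + 1e-3
    event = (rng.random(n) > censor).astype(float)
    if event.sum() == 0:
        event[0] = 1.0
    return SurvivalDataset(
        time=time, event=event, exposure=rng.normal(0, 1, n),
        z=rng.normal(0, 1, (n, p_z)) if p_z else None,
        v=rng.binomial(1, 0.5, (n, p_v)).astype(float) if p_v else None,
    )
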