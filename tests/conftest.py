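import numpy as np
import pytest

from radiosurv.datatypes import PathwaySet, SurvivalLabels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_labels():
    return SurvivalLabels(time=[5.0, 3.0, 8.0, 2.0, 6.0, 1.5],
                          event=[1, 1, 0, 1, 0, 1])


@pytest.fixture
def toy_pathways():
    return PathwaySet({"P1": ["g1", "g2"], "P2": ["g2", "g3"]})


def random_labels(rng, n, censor_frac=0.3):
    """Random untied survival labels for metric oracles."""
    time = rng.exponential(10.0, n) + rng.uniform(0, 1e-3, n)
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return SurvivalLabels(time, event)
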