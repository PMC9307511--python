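import numpy as np
import pytest
from hypothesis import settings

from diffscan import ReactivityDataset, ReactivityProfile

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


def make_profile(values, tx="tx1", cond="A", rep="r1"):
    return ReactivityProfile(tx, cond, rep, np.asarray(values, dtype=float))


def make_dataset(cond_a_values, cond_b_values, tx="tx1"):
    """Dataset from lists of per-replicate value arrays for two conditions."""
    profiles = []
    for i, v in enumerate(cond_a_values):
        profiles.append(make_profile(v, tx=tx, cond="A", rep=f"a{i + 1}"))
    for i, v in enumerate(cond_b_values):
        profiles.append(make_profile(v, tx=tx, cond="B", rep=f"b{i + 1}"))
    return ReactivityDataset(profiles)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def identical_dataset(rng):
    """Two conditions with exactly identical replicate values (global null)."""
    a1, a2 = rng.random(120), rng.random(120)
    return make_dataset([a1, a2], [a1.copy(), a2.copy()])
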