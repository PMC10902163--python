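import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_series(rng, min_len=8, max_len=30, censored=False):
    """A short random series (mix of smooth and rough), optionally with a
    few censored volumes — shared helper for oracle-equivalence tests."""
    n = int(rng.integers(min_len, max_len + 1))
    kind = rng.integers(3)
    if kind == 0:
        x = rng.normal(size=n)
    elif kind == 1:
        x = np.cumsum(rng.normal(size=n))  # smooth random walk
    else:
        x = np.round(rng.normal(size=n), 1)  # ties, boundary-equal distances
    censor = np.zeros(n, dtype=bool)
    if censored:
        k = int(rng.integers(1, max(2, n // 5)))
        censor[rng.choice(n, size=k, replace=False)] = True
    return x, censor
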