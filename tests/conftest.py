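import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def ar1_pair(rng):
    """Two independent zero-mean AR(1) segments with the same coefficient."""
    def make(phi=0.5, n=200, sd=1.0):
        out = []
        for _ in range(2):
            e = rng.standard_normal(n + 200) * sd
            x = np.empty(n + 200)
            x[0] = e[0]
            for t in range(1, n + 200):
                x[t] = phi * x[t - 1] + e[t]
            out.append(x[200:])
        return out
    return make
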