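import numpy as np
import pandas as pd
import pytest

import rankdecomp as rd


@pytest.fixture
def fixture_a():
    """Tiny hand-checkable dataset: four individuals, tied middle ranks.

    y = (10, 20, 20, 40) gives d = (-0.375, 0, 0, 0.375); with
    h = (0.8, 0.4, 0.2, 0.0) the Generalized Concentration Index is -0.15.
    """
    h = np.array([0.8, 0.4, 0.2, 0.0])
    y = np.array([10.0, 20.0, 20.0, 40.0])
    ranks = rd.fractional_ranks(y)
    s = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0]})
    return {"h": h, "y": y, "ranks": ranks, "s": s}


def random_dataset(rng, n=None, k=2, ties=True, weighted=True):
    """Small random dataset for identity/property checks."""
    n = n or int(rng.integers(5, 40))
    y = rng.normal(size=n)
    if ties and n > 6:
        y[rng.integers(0, n)] = y[rng.integers(0, n)]  # occasional tie
    h = rng.normal(size=n)
    w = rng.uniform(0.2, 3.0, size=n) if weighted else np.ones(n)
    X = pd.DataFrame(
        {f"s{j}": rng.normal(size=n) for j in range(k)}
    )
    return h, y, w, X
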