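import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from domaindiff import ExpressionDataset, SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Default synthetic cohort: 200 domains, ~1000 genes, 40+40 samples."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def toy_dataset():
    """4 genes x 6 samples, two conditions of 3, hand-checkable values."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 2.0, 8.0, 5.0],
            "a2": [3.0, 2.0, 9.0, 5.0],
            "a3": [2.0, 2.0, 10.0, 5.0],
            "b1": [4.0, 2.0, 17.0, 0.0],
            "b2": [6.0, 2.0, 19.0, 0.0],
            "b3": [5.0, 2.0, 18.0, 0.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    cond = {s: ("A" if s.startswith("a") else "B") for s in values.columns}
    return ExpressionDataset(values, cond)


def rng_dataset(n_genes, n_per_group, seed, shift_rows=(), shift=0.0):
    """Gaussian log-scale dataset helper used by calibration tests."""
    rng = np.random.default_rng(seed)
    x = rng.normal(8.0, 1.0, size=(n_genes, 2 * n_per_group))
    for r in shift_rows:
        x[r, n_per_group:] += shift
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    values = pd.DataFrame(x - x.min() + 0.1, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    cond = {c: c[0] for c in cols}
    return ExpressionDataset(values, cond)
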