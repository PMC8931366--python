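import numpy as np
import pandas as pd
import pytest

from codevel import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject cohort shared by read-only tests."""
    return generate_cohort(SimConfig(n_subjects=40, seed=11))


def simulate_dm_counts(n, k, j, *, precision=50.0, depth=1000, seed=0,
                       separation=3.0):
    """Well-separated K-component Dirichlet-multinomial data with labels."""
    rng = np.random.default_rng(seed)
    logits = rng.normal(0, 0.5, size=(k, j))
    for kk, idx in enumerate(np.array_split(np.arange(j), k)):
        logits[kk, idx] += separation
    means = np.exp(logits)
    means /= means.sum(axis=1, keepdims=True)
    labels = rng.integers(0, k, size=n)
    x = np.empty((n, j), dtype=np.int64)
    for i, lab in enumerate(labels):
        p = rng.dirichlet(precision * means[lab])
        x[i] = rng.multinomial(depth, p)
    counts = pd.DataFrame(x, index=[f"s{i}" for i in range(n)],
                          columns=[f"t{j_}" for j_ in range(j)])
    return counts, labels
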