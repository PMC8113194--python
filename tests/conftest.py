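import numpy as np
import pandas as pd
import pytest

from parkdx.cohort import default_group_models, generate_cohort


@pytest.fixture(scope="session")
def group_models():
    return default_group_models()


@pytest.fixture(scope="session")
def cohort216():
    """One seeded synthetic cohort at the reference group sizes."""
    return generate_cohort(seed=20240101)


def random_instance(rng: np.random.Generator, n_max=60, f_max=4, k_max=3):
    """Small random classification table with deliberate value ties."""
    n = int(rng.integers(10, n_max + 1))
    f = int(rng.integers(1, f_max + 1))
    k = int(rng.integers(2, k_max + 1))
    cols = {}
    for j in range(f):
        if rng.random() < 0.5:
            # coarse grid -> many tied values and tied split scores
            cols[f"f{j}"] = rng.integers(0, 5, n).astype(float)
        else:
            cols[f"f{j}"] = rng.normal(size=n)
    df = pd.DataFrame(cols)
    df["group"] = [f"C{int(i)}" for i in rng.integers(0, k, n)]
    return df, [f"f{j}" for j in range(f)]
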