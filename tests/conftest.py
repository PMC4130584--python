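import numpy as np
import pandas as pd
import pytest

import layerome as L


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded benchmark with the default planted up-cytoplasm term."""
    return L.simulate_dataset(L.SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    b = default_bundle
    return L.run_analysis(b.dataset, b.network.edges(data="confidence"), b.locmap, b.catalog)


def make_dataset(values: dict[str, list[float]], n_a: int, n_b: int) -> L.ExpressionDataset:
    """Small expression dataset: first n_a samples are groupA."""
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    frame = pd.DataFrame(values, index=samples).T
    cond = pd.Series(["groupA"] * n_a + ["groupB"] * n_b, index=samples)
    return L.ExpressionDataset(values=frame, condition=cond, group_a="groupA")


@pytest.fixture
def rng():
    return np.random.default_rng(20240812)
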