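import numpy as np
import pytest

from diffstab import CovariateMatrix, StabilityDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_condition_X():
    """Six samples, two conditions (3 vs 3)."""
    return CovariateMatrix(X=np.repeat([0.0, 1.0], 3)[:, None], names=["condition"])


@pytest.fixture
def small_dataset(rng):
    G, n = 30, 6
    return StabilityDataset(
        gene_ids=[f"g{i}" for i in range(G)],
        exonic_counts=rng.poisson(50, size=(G, n)),
        intronic_counts=rng.poisson(20, size=(G, n)),
        sample_ids=[f"s{j}" for j in range(n)],
    )
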