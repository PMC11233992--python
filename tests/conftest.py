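import numpy as np
import pytest

from ecostatus import SyntheticConfig, generate_dataset, index_table


@pytest.fixture(scope="session")
def default_dataset():
    """The reference design: 8 good / 20 non-good samples, seed 1."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_table(default_dataset):
    return index_table(default_dataset)


@pytest.fixture(scope="session")
def random_assemblages():
    """200 random integer assemblages spanning the index domains."""
    rng = np.random.default_rng(42)
    out = []
    for _ in range(200):
        S = int(rng.integers(2, 40))
        counts = rng.integers(1, 500, size=S)
        out.append({f"sp{i}": float(c) for i, c in enumerate(counts)})
    return out
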