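import numpy as np
import pytest

from phenet.model import MultiModalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, n=20, d=8, m=2, stages=("HC", "MD", "SD")):
    """Random small multi-modal dataset with cycling stage labels."""
    X = [rng.standard_normal((n, d)) for _ in range(m)]
    y = rng.integers(0, 3, n).astype(float)
    labels = [stages[i % len(stages)] for i in range(n)]
    tags = ["node", "edge", "extra"][:m]
    return MultiModalDataset(
        X=X, y=y, stages=labels,
        roi_names=[f"r{j}" for j in range(d)], modalities=tags,
    )


@pytest.fixture
def tiny_dataset(rng):
    return make_dataset(rng)
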