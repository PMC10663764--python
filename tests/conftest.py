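import numpy as np
import pytest

from nmanova import DissimilarityMatrix, Partition


@pytest.fixture
def worked_matrix() -> DissimilarityMatrix:
    """3x3 matrix with three singleton groups; every sampling pool is forced."""
    return DissimilarityMatrix(
        [[1, 5, 6], [4, 2, 7], [8, 9, 3]], ids=["a", "b", "c"]
    )


@pytest.fixture
def worked_partition() -> Partition:
    return Partition(["g1", "g2", "g3"], ids=["a", "b", "c"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_block_inputs(rng, sizes=(3, 4, 5), missing=0.0):
    """Helper: iid-entry matrix + group-major partition, optional missingness."""
    n = sum(sizes)
    vals = rng.normal(size=(n, n))
    if missing:
        vals[rng.random((n, n)) < missing] = np.nan
    labels = np.repeat(np.arange(len(sizes)), sizes)
    m = DissimilarityMatrix(vals)
    return m, Partition(labels.tolist(), ids=m.ids)
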