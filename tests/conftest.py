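import numpy as np
import pytest

from firescore.matrix import RawCountMatrix


@pytest.fixture
def tiny_counts() -> RawCountMatrix:
    """4 cells x 3 genes with hand-checkable structure."""
    counts = np.array(
        [
            [3, 0, 5],
            [3, 2, 0],
            [3, 2, 1],
            [0, 2, 4],
        ]
    )
    return RawCountMatrix(counts, [f"c{i}" for i in range(4)],
                          ["gA", "gB", "gC"])


@pytest.fixture
def random_counts() -> RawCountMatrix:
    """60 cells x 40 genes of seeded Poisson counts."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(3.0, size=(60, 40))
    return RawCountMatrix(counts, [f"c{i}" for i in range(60)],
                          [f"g{j}" for j in range(40)])
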