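import numpy as np
import pytest

from refstab import CtMatrix


def make_matrix(ct, genes=None, samples=None):
    ct = np.asarray(ct, dtype=float)
    k, n = ct.shape
    genes = genes or [f"g{i + 1}" for i in range(k)]
    samples = samples or [f"s{j + 1}" for j in range(n)]
    return CtMatrix(genes, samples, ct)


@pytest.fixture
def toy_matrix():
    """Three genes over three samples; the first two share shape, the third
    is flatter — the standard worked example for the stability methods."""
    return make_matrix(
        [[20.0, 20.0, 20.0], [22.0, 23.0, 24.0], [30.0, 30.0, 31.0]],
        genes=["A", "B", "C"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
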