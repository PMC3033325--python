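import numpy as np
import pytest

from ldforest import Coding, SnpMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_matrix():
    """Six SNPs: two blocks of three perfectly correlated columns."""
    r = np.random.default_rng(7)
    a = r.integers(0, 2, size=500)
    b = r.integers(0, 2, size=500)
    values = np.column_stack([a, a, a, b, b, b])
    return SnpMatrix(values, Coding.haplotype_01,
                     marker_names=[f"S{i}" for i in range(1, 7)])


def toy_forest():
    """Three-layer toy: H2_1 over (H1_1 over S1,S2) and (H1_2 over S3,S4);
    S5 isolated."""
    from ldforest import Forest

    f = Forest()
    for nid in ["S1", "S2", "S3", "S4", "S5"]:
        f.add_observed(nid, 2, prior=np.array([0.5, 0.5]))
    cpt = np.array([[0.9, 0.1], [0.1, 0.9]])
    uniform = np.array([0.5, 0.5])
    n = 8
    f.add_latent("H1_1", 2, ["S1", "S2"], uniform, [cpt, cpt],
                 np.zeros(n, dtype=np.int64))
    f.add_latent("H1_2", 2, ["S3", "S4"], uniform, [cpt, cpt],
                 np.ones(n, dtype=np.int64))
    f.add_latent("H2_1", 2, ["H1_1", "H1_2"], uniform, [cpt, cpt],
                 np.zeros(n, dtype=np.int64))
    return f
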