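import numpy as np
import pytest

from rerankfs import SimDesign, feature_matrix, gaussian_two_group


@pytest.fixture
def tiny_pair():
    """One case row [5,1], one control row [1,5]: the worked centering example."""
    return feature_matrix([[5.0, 1.0], [1.0, 5.0]], [1, 0])


@pytest.fixture
def tied_triplet():
    """2x2 case/control blocks with tied zeros: the worked midrank example."""
    return feature_matrix(
        [[10.0, 0.0, 0.0], [8.0, 0.0, 0.0], [0.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
        [1, 1, 0, 0],
    )


@pytest.fixture
def null_matrix():
    """Case block an exact copy of the control block: the global null."""
    rng = np.random.default_rng(42)
    block = rng.standard_normal((5, 12))
    return feature_matrix(np.vstack([block, block]), np.repeat([1, 0], 5))


@pytest.fixture
def small_signal():
    """40 markers, 3 of them strongly shifted, 10 + 10 subjects."""
    design = SimDesign(p=40, m_star=3, delta=3.0, n1=10, n0=10, seed=7)
    return gaussian_two_group(design)
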