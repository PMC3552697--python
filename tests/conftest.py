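import numpy as np
import pandas as pd
import pytest

from ctnorm import CTMatrix, generate_ct


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples, complete, hand-sized."""
    data = pd.DataFrame(
        [[20.0, 21.0, 19.5, 20.5],
         [25.0, 26.0, 24.0, 25.5],
         [30.0, 32.0, 29.0, 31.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"])
    return CTMatrix(data)


@pytest.fixture
def two_gene_matrix():
    """The worked weighted-mean example: sds sqrt(2) and sqrt(1/2)."""
    data = pd.DataFrame([[10.0, 12.0], [20.0, 21.0]],
                        index=["g1", "g2"], columns=["s1", "s2"])
    return CTMatrix(data)


@pytest.fixture
def missing_matrix():
    data = pd.DataFrame(
        [[20.0, 21.0, np.nan, 20.5],
         [25.0, 26.0, 24.0, 25.5],
         [np.nan, np.nan, np.nan, 31.0],
         [22.0, 22.5, 21.5, 22.0]],
        index=["gA", "gB", "gC", "gD"], columns=["s1", "s2", "s3", "s4"])
    return CTMatrix(data)


@pytest.fixture(scope="session")
def synth_default():
    """Default study conditions: 666 genes x 20 samples, seeded."""
    return generate_ct(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
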