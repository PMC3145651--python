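import numpy as np
import pandas as pd
import pytest

import plsnet as P


@pytest.fixture(scope="session")
def separable7():
    return P.make_fixture("separable7")


@pytest.fixture(scope="session")
def null_fixture():
    return P.make_fixture("null")


@pytest.fixture(scope="session")
def paperlike():
    return P.make_fixture("paperlike")


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, labels 1,1,0,0."""
    values = pd.DataFrame(
        [[2.0, 4.0, 1.0, 3.0], [1.0, 1.0, 1.0, 1.0], [5.0, 6.0, 2.0, 1.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return P.ExpressionDataset(values, np.array([1, 1, 0, 0]))


def write_tsv(path, text):
    path.write_text(text)
    return path
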