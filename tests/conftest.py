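import numpy as np
import pandas as pd
import pytest

from dualrepress.expression import ExpressionMatrix
from dualrepress.seeds import MirnaRecord


def make_matrix(values, condition, detected=None, genes=None):
    """Small ExpressionMatrix from a dict/array of columns."""
    df = pd.DataFrame(values)
    if genes is not None:
        df.index = genes
    else:
        df.index = [f"g{i}" for i in range(len(df))]
    if detected is None:
        det = pd.DataFrame(True, index=df.index, columns=df.columns)
    else:
        det = pd.DataFrame(detected, index=df.index, columns=df.columns).astype(bool)
    return ExpressionMatrix(values=df, detected=det, condition=dict(condition))


@pytest.fixture
def toy_3v2():
    """3-vs-2 matrix: two strong planted genes among flat nulls."""
    rng = np.random.default_rng(42)
    n = 40
    log2 = rng.normal(8, 0.2, size=(n, 5))
    log2[0, 3:] += 4.0  # up in B
    log2[1, 3:] -= 4.0  # down in B
    values = {s: 2.0 ** log2[:, j] for j, s in enumerate(["A1", "A2", "A3", "B1", "B2"])}
    return make_matrix(values, {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B"})


@pytest.fixture
def mirna():
    return MirnaRecord(id="mir-test", sequence="AAAGTGCTTCCCTTTTGTGTGT")
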