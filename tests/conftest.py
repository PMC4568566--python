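import numpy as np
import pandas as pd
import pytest

from sigscore.containers import ExpressionMatrix, SampleGroups


@pytest.fixture
def tiny_log2_matrix():
    """3 genes x 6 samples log2 matrix with two groups of 3."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(3, 6)),
        index=["GA", "GB", "GC"],
        columns=[f"S{i}" for i in range(1, 7)],
    )
    return ExpressionMatrix(df, scale="log2", feature_level="gene")


@pytest.fixture
def two_groups():
    return SampleGroups(
        {f"S{i}": ("CTRL" if i <= 3 else "TREATED") for i in range(1, 7)},
        reference_group="CTRL",
    )
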