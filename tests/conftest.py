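import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_expression(cluster_values: dict[str, list[float]], gene: str = "g") -> tuple[pd.DataFrame, pd.Series]:
    """Single-gene expression matrix from per-cluster value lists."""
    values, labels, cols = [], [], []
    i = 0
    for cluster, vals in cluster_values.items():
        for v in vals:
            values.append(v)
            labels.append(cluster)
            cols.append(f"cell{i}")
            i += 1
    norm = pd.DataFrame([values], index=[gene], columns=cols, dtype=float)
    return norm, pd.Series(labels, index=cols)


@pytest.fixture
def toy_expression():
    return make_expression
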