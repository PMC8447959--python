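import numpy as np
import pandas as pd
import pytest

from circsponge.matrix import ExpressionMatrix


def make_matrix(values, scale="log2", group_split=None):
    """Small ExpressionMatrix helper: values is a 2D array-like; samples are
    named s1..sk and split evenly into groups a/b unless group_split given."""
    arr = np.asarray(values, dtype=float)
    n_probes, n_samples = arr.shape
    samples = [f"s{j+1}" for j in range(n_samples)]
    split = group_split if group_split is not None else n_samples // 2
    groups = {s: ("a" if j < split else "b") for j, s in enumerate(samples)}
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=[f"p{i+1}" for i in range(n_probes)], columns=samples),
        scale=scale,
        groups=groups,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_log2_matrix(rng):
    return make_matrix(rng.normal(8, 1.5, size=(40, 6)))
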