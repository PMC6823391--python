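import numpy as np
import pandas as pd
import pytest

from rgcmark import ExpressionMatrix, SimConfig, generate_dataset


def make_matrix(values, probes=None, cells=None, scale_tag="mas5_linear"):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"p{i+1}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j+1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=probes, columns=cells), scale_tag)


def log2_matrix(values, probes=None, cells=None):
    """Matrix whose log2(x+1) transform equals ``values`` exactly."""
    arr = np.exp2(np.asarray(values, dtype=float)) - 1.0
    return make_matrix(arr, probes, cells)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across read-only tests."""
    cfg = SimConfig(seed=0)
    matrix, annotations, truth, probe_map = generate_dataset(cfg)
    return cfg, matrix, annotations, truth, probe_map


@pytest.fixture()
def groups_of(default_dataset):
    _, _, annotations, _, _ = default_dataset
    return {a.cell_id: a.group for a in annotations}
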