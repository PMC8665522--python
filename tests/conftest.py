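import numpy as np
import pandas as pd
import pytest

import cernapivot as cp


def make_matrix(values, unit="fpkm", biotypes=None, lengths=None, conditions=None):
    """Small ExpressionMatrix builder for hand-made fixtures.

    ``values``: 2-D array-like (genes x samples).  Gene ids G1.., sample ids
    S1..; first half of samples tumor, second half control unless given.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"G{i+1}" for i in range(n_genes)]
    samples = [f"S{j+1}" for j in range(n_samples)]
    if conditions is None:
        half = n_samples // 2
        conditions = ["tumor"] * half + ["control"] * (n_samples - half)
    return cp.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        lengths=pd.Series(lengths if lengths is not None else [1000] * n_genes,
                          index=genes),
        biotypes=pd.Series(biotypes if biotypes is not None
                           else ["mRNA"] * n_genes, index=genes),
        samples=pd.DataFrame({"condition": conditions}, index=samples),
        unit=unit,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic dataset shared across tests."""
    config = cp.SimulationConfig(seed=7)
    matrix, truth = cp.simulate_expression(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def default_fpkm(default_dataset):
    _, matrix, _ = default_dataset
    return cp.compute_fpkm(matrix)


@pytest.fixture(scope="session")
def default_de(default_fpkm):
    return cp.classify_de(cp.test_differential(default_fpkm))
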