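import numpy as np
import pandas as pd
import pytest

from migex.expression_io import ExpressionDataset
from migex.synthetic_data import default_bundle_config, generate_study_bundle


def make_dataset(matrix, groups, batches=None, genes=None, name="fixture"):
    """Build a small ExpressionDataset from plain lists."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    batches = batches or ["0"] * n_samples
    return ExpressionDataset(
        pd.DataFrame(matrix, index=genes, columns=samples),
        groups=pd.Series(list(groups), index=samples),
        batches=pd.Series(list(batches), index=samples),
        name=name,
    )


@pytest.fixture(scope="session")
def bundle():
    """One fixed-seed synthetic study bundle shared across tests."""
    return generate_study_bundle(default_bundle_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240210)
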