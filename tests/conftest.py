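import numpy as np
import pandas as pd
import pytest

from celldiv.core import ExpressionMatrix, GeneTable
from celldiv.simulate import default_config, simulate_expression


def make_expression(values: np.ndarray, populations, unit="fpkm", genes=None, order=None):
    """Small helper to build an ExpressionMatrix from a raw array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    samp = pd.DataFrame(
        {
            "population": list(populations),
            "order": list(order) if order is not None else list(range(n_samples)),
        },
        index=pd.Index(samples, name="sample"),
    )
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(vals, samp, unit=unit)


@pytest.fixture
def small_em():
    """3 genes x 4 samples, 2 populations of 2 replicates."""
    return make_expression(
        [[1.0, 2.0, 10.0, 12.0], [5.0, 5.0, 5.0, 5.0], [0.0, 0.0, 3.0, 3.0]],
        populations=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """Default-condition simulation shared by pipeline-level tests."""
    cfg = default_config(seed=11)
    em, gt, truth = simulate_expression(cfg)
    return cfg, em, gt, truth
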