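import numpy as np
import pandas as pd
import pytest

import pifrif as p


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-structure dataset shared across read-only tests."""
    cfg = p.SimulationConfig(
        n_genes=2000,
        mito_set_size=300,
        n_regulators=50,
        n_rewired=2,
        rng_seed=42,
    )
    return p.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_expression(small_sim):
    return p.normalize_counts(small_sim.counts)


@pytest.fixture(scope="session")
def small_de(small_expression):
    return p.compute_de(small_expression)


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        {
            "HFE_1": [5, 0, 3, 8, 1],
            "HFE_2": [2, 4, 6, 0, 2],
            "LFE_1": [7, 1, 9, 3, 4],
            "LFE_2": [1, 2, 5, 6, 8],
        },
        index=[f"g{i}" for i in range(5)],
    )
    groups = pd.Series(
        ["HFE", "HFE", "LFE", "LFE"], index=counts.columns, name="group"
    )
    return p.CountMatrix(counts=counts, groups=groups)


def make_expression(values: np.ndarray, groups_list, genes=None):
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = [f"s{i}" for i in range(n_s)]
    return p.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(groups_list, index=samples, name="group"),
        provenance=["test"],
    )
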