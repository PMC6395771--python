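import numpy as np
import pandas as pd
import pytest

from strianet import preprocess as pp
from strianet import simulate as sim


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated case/control dataset with one disrupted module."""
    design = sim.SyntheticDesign(
        n_genes=600,
        n_case=20,
        n_control=20,
        module_sizes=[80, 100],
        module_loadings=0.8,
        disrupted_module=1,
        n_deg=30,
        deg_log2fc=2.0,
        dispersion=0.05,
        seed=42,
    )
    counts_case, counts_ctrl, metadata, truth = sim.simulate_dataset(design)
    counts = pd.concat([counts_case, counts_ctrl], axis=1)
    return {
        "design": design,
        "counts": counts,
        "counts_case": counts_case,
        "counts_control": counts_ctrl,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_expression(small_dataset):
    expr = pp.normalize_log(small_dataset["counts"])
    meta = small_dataset["metadata"]
    return {
        "expr": expr,
        "expr_case": expr[meta.index[meta["group"] == "case"]],
        "expr_control": expr[meta.index[meta["group"] == "control"]],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
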