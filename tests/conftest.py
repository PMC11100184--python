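import numpy as np
import pandas as pd
import pytest

from mrnet import (
    ExpressionMatrix,
    SimulationConfig,
    mr_from_expression,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_expr():
    """Hand-sized 5-gene x 6-sample TPM matrix with one constant gene."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.uniform(1, 50, size=(5, 6)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
    values.loc["g4"] = 7.0  # constant profile
    return ExpressionMatrix(values=values)


@pytest.fixture(scope="session")
def default_sim():
    """The default planted-module study conditions at seed 1."""
    cfg = SimulationConfig(seed=1)
    expr, truth = simulate_expression(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def default_matrices(default_sim):
    _, expr, _ = default_sim
    return mr_from_expression(expr)


@pytest.fixture(scope="session")
def deg_sim():
    """Two-condition matrix with 50 planted 4x up-shifted genes of 500."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=500,
        n_modules=5,
        module_size=10,
        within_module_corr=0.0,
        group_labels=("treated", "control"),
        group_sizes=(5, 5),
        module_group_shifts={m: {"treated": 2.0} for m in range(5)},
    )
    expr, truth = simulate_expression(cfg)
    return cfg, expr, truth
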