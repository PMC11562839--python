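import numpy as np
import pytest

import brilliant as b


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Small simulated replicate: 4 predictor groups of 5, 2 response
    groups of 3, strong signal."""
    cfg = b.SimulationConfig(
        n_train=60,
        n_val=30,
        n_test=30,
        x_group_sizes=(5,) * 4,
        y_group_sizes=(3,) * 2,
        rho_x=0.5,
        rho_e=0.5,
        nonzero_block_frac=0.25,
        seed=7,
    )
    return b.simulate_dataset(cfg)


@pytest.fixture
def small_model(small_sim):
    Xtr, Ytr = small_sim.split("train")
    return b.BrilliantModel(
        Ytr,
        Xtr,
        x_groups=small_sim.x_groups,
        y_groups=small_sim.y_groups,
        precision="block",
    )


@pytest.fixture
def tiny_structures():
    """p=6 in 2 groups, q=4 in 2 groups, n=30 design with named frames."""
    import pandas as pd

    rng = np.random.default_rng(3)
    p, q, n = 6, 4, 30
    xnames = [f"x{j}" for j in range(p)]
    ynames = [f"y{k}" for k in range(q)]
    xg = b.GroupStructure(xnames, {"A": xnames[:3], "B": xnames[3:]})
    yg = b.GroupStructure(ynames, {"a": ynames[:2], "b": ynames[2:]})
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=xnames,
                     index=[f"s{i}" for i in range(n)])
    Btrue = np.zeros((p, q))
    Btrue[0, 0] = 2.0
    Btrue[4, 3] = -1.5
    Y = pd.DataFrame(
        X.to_numpy() @ Btrue + 0.3 * rng.standard_normal((n, q)),
        columns=ynames, index=X.index,
    )
    return X, Y, xg, yg, Btrue
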