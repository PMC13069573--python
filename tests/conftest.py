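import numpy as np
import pandas as pd
import pytest

from exprvar.io import ExpressionPanel
from exprvar.simulate import SimulationDesign, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study shared by read-only tests."""
    design = SimulationDesign(n_singletons=120, n_ssd_pairs=40,
                              n_wgd_pairs=40, n_timepoints=4, seed=11)
    return simulate_all(design)


@pytest.fixture
def toy_panel():
    """3 genes x 2 individuals x 2 timepoints, fully observed."""
    rng = np.random.default_rng(0)
    values = rng.uniform(1, 100, size=(3, 2, 2))
    return ExpressionPanel(["gA", "gB", "gC"], ["i1", "i2"],
                           ["t1", "t2"], values)
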