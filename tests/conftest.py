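import numpy as np
import pandas as pd
import pytest

import cytoflmm as cf


@pytest.fixture(scope="session")
def grid():
    return np.arange(1.0, 73.0)


@pytest.fixture(scope="session")
def quad_weights(grid):
    w = np.zeros_like(grid)
    w[:-1] += np.diff(grid) / 2
    w[1:] += np.diff(grid) / 2
    return w


@pytest.fixture(scope="session")
def small_design():
    """A light design: 6 + 4 chemicals, 11 concentrations, 4 controls."""
    return cf.SimulationDesign(n_group1=6, n_group10=4, n_other=0, n_controls=4)


@pytest.fixture(scope="session")
def small_truth(small_design):
    return cf.make_truth(small_design, seed=101)


@pytest.fixture(scope="session")
def small_panel(small_truth, small_design):
    return cf.simulate_panel(small_truth, small_design, seed=101)


@pytest.fixture(scope="session")
def basis(grid):
    return cf.make_bspline_basis(domain=(0.0, 72.0), grid=grid)


def make_tiny_panel(curves, grid, levels=None, chem_ids=None, conc=None, reps=None, moa=None):
    """Construct a minimal binned panel from explicit curve rows."""
    curves = np.asarray(curves, dtype=float)
    n = curves.shape[0]
    obs = pd.DataFrame(
        {
            "chemical_id": chem_ids or [f"c{i}" for i in range(n)],
            "moa_label": moa or [None] * n,
            "concentration_index": conc or [1] * n,
            "binned_level": levels or ["high"] * n,
            "replicate_index": reps or list(range(1, n + 1)),
        }
    )
    return cf.CurvePanel(grid=np.asarray(grid, float), values=curves, obs=obs)
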