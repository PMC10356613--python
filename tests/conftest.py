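import numpy as np
import pandas as pd
import pytest

from nephroniche import simulate as sim
from nephroniche import scoring


@pytest.fixture(scope="session")
def expr_draw():
    """Moderate expression draw with planted universal and partial markers."""
    cfg = sim.ExpressionConfig(
        seed=11, cells_per_group=30, n_genes=400,
        partial_marker_subclasses=("PT",), n_partial_markers=10,
    )
    return sim.simulate_expression(cfg)


@pytest.fixture(scope="session")
def norm_expr(expr_draw):
    adata, truth = expr_draw
    return scoring.normalize_counts(adata), truth


@pytest.fixture(scope="session")
def bead_field_null():
    return sim.simulate_beads(sim.BeadConfig(seed=7))


@pytest.fixture(scope="session")
def bead_field_planted():
    pref = ((5.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
    return sim.simulate_beads(sim.BeadConfig(seed=7, preference=pref))


@pytest.fixture(scope="session")
def spots_default():
    return sim.simulate_spots(sim.SpotConfig.default(seed=13, n_spots=1000))


@pytest.fixture(scope="session")
def spots_tal():
    return sim.simulate_spots(sim.SpotConfig.tal_niches(seed=13, n_spots=1200))


@pytest.fixture(scope="session")
def cells3d_small():
    # quarter-size field at the default density (~26 cells / neighborhood)
    return sim.simulate_cells3d(sim.Cells3DConfig(
        seed=5, n_cells=2500, box=(200.0, 200.0, 100.0), niche_radius=65.0))


@pytest.fixture(scope="session")
def peaks_planted():
    return sim.simulate_peaks(sim.PeakConfig(seed=3))


@pytest.fixture(scope="session")
def traj_draw():
    return sim.simulate_trajectory(sim.TrajectoryConfig(seed=3))
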