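import numpy as np
import pytest

import phylograin as pg


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — the canonical hand-computable tree."""
    return pg.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_forest():
    """A deterministic 20-species neutral forest on a 50 m plot."""
    tree = pg.simulate_phylogeny(20, seed=11)
    dem = pg.simulate_dem(50, 5, relief_amplitude=8.0, seed=12)
    stems = pg.simulate_stem_map(
        tree, dem, 1500, scenario=pg.AssemblyScenario(seed=13)
    )
    return tree, dem, stems


def plane_dem(n=10, cell=1.0, gx=0.0, gy=0.0, base=100.0):
    """DEM whose elevation is the plane base + gx*x + gy*y (cell centers)."""
    xs = (np.arange(n) + 0.5) * cell
    xg, yg = np.meshgrid(xs, xs)
    return pg.DemGrid(base + gx * xg + gy * yg, cell)
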