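"""Hegyi competition index per stem and per quadrat.

CI_i = sum over neighbors j within the radius of (DBH_j / DBH_i) / dist_ij:
big close neighbors crowd a small focal tree the most.
"""

import phylograin as pg
from phylograin.competition import hegyi_ci, quadrat_ci

tree = pg.simulate_phylogeny(50, seed=9)
dem = pg.simulate_dem(100, 5, 15, seed=10)
stems = pg.simulate_stem_map(tree, dem, 5000, scenario=pg.AssemblyScenario(seed=11))

records = hegyi_ci(stems, radius=5.0)
print("per-stem CI at a 5 m radius:")
print(records["CI"].describe().round(3).to_string())

means = quadrat_ci(records, stems, pg.QuadratGrid(100, 5), stage="sapling")
print(f"\nquadrat-mean sapling CI: defined in {means.notna().sum()} of {len(means)} quadrats")
print(means.dropna().describe().round(3).to_string())
# Saplings typically carry the largest CI: their small DBH sits in the
# denominator of every neighbor ratio.
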