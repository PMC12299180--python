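"""Per-quadrat phylogenetic structure under the taxa-shuffle null.

Simulates a forest assembled by environmental filtering along elevation,
computes SR, Faith's PD and the NRI/NTI per 5 m quadrat, and summarizes
the mean effect sizes per life stage — positive NRI means the quadrats
hold closer relatives than random draws from the species pool.
"""

import phylograin as pg
from phylograin.forest_io import QuadratGrid, build_community_matrix
from phylograin.phylo import NullModelConfig, ses_metrics, stage_summary

tree = pg.simulate_phylogeny(104, seed=5)
dem = pg.simulate_dem(100, 5, relief_amplitude=20, seed=6)
stems = pg.simulate_stem_map(
    tree, dem, 8000,
    scenario=pg.AssemblyScenario(mode="filtering", intensity=3.0, seed=7),
)

rows = []
for stage in (None, "sapling", "juvenile", "adult"):
    cm = build_community_matrix(stems, QuadratGrid(100, 5), stage=stage)
    rows.append(ses_metrics(cm, tree, NullModelConfig(n_rand=199, seed=8)))

import pandas as pd

summary = stage_summary(pd.concat(rows, ignore_index=True))
print(summary.round(3).to_string(index=False))
# Under filtering, quadrats on the same part of the gradient collect
# species with similar (phylogenetically conserved) affinities, pushing
# NRI/NTI positive.  The tip-level NTI responds most reliably; the
# deep-branch NRI is noisier between realizations, because one species
# with an extreme affinity draw can dominate the steepest cells and
# offset it — averaging over replicate forests recovers the positive sign.
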