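"""Derive terrain covariates from a DEM and aggregate them to quadrats.

Computes slope, southness aspect score, TPI, TRI, roughness and D8 flow
accumulation for a synthetic DEM, then averages them over the 5 m quadrat
grid and z-scores them — the covariate table the mixed models consume.
"""

import phylograin as pg
from phylograin import terrain

dem = pg.simulate_dem(side=100, cell=5, relief_amplitude=20, seed=4)
layers = terrain.compute_terrain_layers(dem)
grid = pg.QuadratGrid(side=100, scale=5)
covariates = terrain.quadrat_terrain(layers, grid)

print(f"{len(covariates)} quadrats at {grid.scale} m")
print(covariates.describe().loc[["mean", "std", "min", "max"]].round(3).to_string())

z = terrain.zscore(covariates)
print("\nafter z-scoring (each column mean 0, sd 1):")
print(z.mean().round(6).to_string())
# TPI > 0 marks local ridges, TPI < 0 depressions; the flowdir column is
# log10(1 + upstream cell count), a monotone wetness proxy.
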