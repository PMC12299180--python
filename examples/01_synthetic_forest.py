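"""Generate a synthetic stem-mapped forest and look at its census structure.

Builds a 104-species pure-birth phylogeny, a smooth DEM, and a 20 000-stem
census on a 340 m plot under neutral assembly, then prints the stage
composition and dominance structure a field crew would tabulate first.
"""

import phylograin as pg

tree = pg.simulate_phylogeny(n_species=104, seed=1)
dem = pg.simulate_dem(side=340, cell=5, relief_amplitude=30, seed=2)
stems = pg.simulate_stem_map(
    tree, dem, n_stems=20000, scenario=pg.AssemblyScenario(mode="neutral", seed=3)
)

stages = pg.forest_io.life_stages(stems["dbh_cm"])
print(f"{len(stems)} stems, {stems['species'].nunique()} species")
print("stage composition (fraction of stems):")
print(stages.value_counts(normalize=True).round(3).to_string())
top = stems["species"].value_counts().head(4)
print("four most abundant species (stem counts):")
print(top.to_string())
# A realistic census is dominated by saplings/juveniles and a handful of
# abundant species; the DBH distribution is right-skewed above the 1 cm floor.
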