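"""Synthetic forests with known community-assembly structure.

Every downstream stage of the pipeline (tiling, terrain covariates,
NRI/NTI null models, Hegyi competition, mixed models) can be exercised on
forests generated here: a pure-birth time-calibrated phylogeny, a smooth
DEM, and a stem map placed under one of three assembly scenarios —

* ``neutral``     — uniform placement, species drawn from a fixed
  rank-abundance distribution; the null the randomization tests assume.
* ``filtering``   — species sort along an environmental gradient with a
  phylogenetically conserved (Brownian) affinity, so close relatives
  co-occur and quadrats are phylogenetically clustered (NRI > 0).
* ``repulsion``   — sequential placement penalizing phylogenetically
  close neighbors within 10 m, producing overdispersion (NRI < 0).

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from phylograin.forest_io import DemGrid

#: Radius (m) of the phylogenetic-repulsion neighborhood; covers the
#: largest analysis grain (10 m).
REPULSION_RADIUS_M = 10.0

#: Geometric rank-abundance ratio: species of rank k has relative
#: abundance q**k.  q = 0.93 gives a realistic dominance structure for a
#: ~100-species plot (the top four species hold about a quarter of stems).
ABUNDANCE_RATIO = 0.93


class AssemblyMode(str, enum.Enum):
    NEUTRAL = "neutral"
    FILTERING = "filtering"
    REPULSION = "repulsion"


@dataclass(frozen=True)
class AssemblyScenario:
    """Which assembly process shapes the stem map, and how strongly.

    ``intensity`` = 0 collapses every mode to the neutral process (the
    generators dispatch to the same code path, so outputs are
    bit-identical).  ``env_covariate`` selects the gradient filtering
    acts along.
    """

    mode: AssemblyMode | str = AssemblyMode.NEUTRAL
    intensity: float = 0.0
    env_covariate: str = "elevation"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", AssemblyMode(self.mode))
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.env_covariate not in {"elevation", "tpi", "flowdir"}:
            raise ValueError(f"unknown env_covariate {self.env_covariate!r}")


@dataclass(frozen=True)
class DbhModel:
    """Right-skewed DBH distribution: ``min_dbh + LogNormal(log_mean, log_sd)``.

    The defaults (1 + exp(N(1.4, 1.0)) cm) put roughly half the stems in
    the sapling bin (<5 cm), ~40% in the juvenile bin (5-15 cm) and ~10%
    in the adult bin (>=15 cm) — a community dominated by saplings and
    juveniles with relatively few adults, as typical of censused
    broad-leaved stands.
    """

    log_mean: float = 1.4
    log_sd: float = 1.0
    min_dbh: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.min_dbh + rng.lognormal(self.log_mean, self.log_sd, size=n)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule, rate 1) phylogeny with depth rescaled to 1.0.

    The returned tree is rooted, binary and ultrametric, with tips
    labelled ``sp001`` .. ``spNNN``; same ``(n_species, seed)`` gives an
    identical Newick string.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    # Birth times: with k lineages the next split waits Exp(k); a final
    # Exp(n) interval separates the last split from the present, so every
    # branch length is strictly positive.
    times = [0.0]
    t = 0.0
    for k in range(2, n_species):
        t += rng.exponential(1.0 / k)
        times.append(t)
    total = t + rng.exponential(1.0 / n_species)

    tree = dendropy.Tree()
    tree.is_rooted = True
    active = []
    for _ in range(2):  # root split at time 0
        child = tree.seed_node.new_child()
        child.birth_time = 0.0
        active.append(child)
    for split_t in times[1:]:
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = split_t - node.birth_time
        for _ in range(2):
            child = node.new_child()
            child.birth_time = split_t
            active.append(child)
    for leaf in active:
        leaf.edge.length = total - leaf.birth_time

    # depth-1 rescale and deterministic tip labels
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= total
    tree.seed_node.edge.length = None
    width = len(str(n_species))
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = ns.new_taxon(f"sp{i:0{width}d}")
        leaf.taxon = taxon
    tree.taxon_namespace = ns
    return tree


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------

def simulate_dem(
    side: float,
    cell: float,
    relief_amplitude: float,
    seed: int,
    trend: tuple[float, float] = (0.05, 0.08),
    base_elevation: float = 800.0,
    smoothing_cells: float = 4.0,
) -> DemGrid:
    """Smooth synthetic DEM: planar trend plus low-pass Gaussian relief.

    ``trend`` is the (d z/d x, d z/d y) plane gradient in m/m;
    ``relief_amplitude`` is the peak-to-trough range (m) of the smoothed
    noise component.  ``side`` must be divisible by ``cell``.
    """
    from scipy.ndimage import gaussian_filter

    n = side / cell
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"side {side} not divisible by cell {cell}")
    n = int(round(n))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    smooth = gaussian_filter(noise, sigma=smoothing_cells, mode="nearest")
    span = smooth.max() - smooth.min()
    if relief_amplitude > 0 and span > 0:
        smooth = (smooth - smooth.min()) / span * relief_amplitude
    else:
        smooth = np.zeros_like(smooth)
    xs = (np.arange(n) + 0.5) * cell
    ys = (np.arange(n) + 0.5) * cell
    xg, yg = np.meshgrid(xs, ys)
    values = base_elevation + trend[0] * xg + trend[1] * yg + smooth
    return DemGrid(values=values, cellsize=cell, xll=0.0, yll=0.0)


# ---------------------------------------------------------------------------
# Stem maps
# ---------------------------------------------------------------------------

def _rank_abundance(n_species: int, rng: np.random.Generator) -> np.ndarray:
    """Geometric rank-abundance probabilities, ranks permuted over species."""
    p = ABUNDANCE_RATIO ** np.arange(n_species)
    p /= p.sum()
    return p[rng.permutation(n_species)]


def _brownian_affinity(tree: dendropy.Tree, labels: list[str],
                       rng: np.random.Generator) -> np.ndarray:
    """Tip values of a Brownian trait (variance 1), z-scored across species.

    Brownian covariance between two tips of an ultrametric tree equals
    their shared path length to the root = depth - d_ij / 2.
    """
    from phylograin.phylo import cophenetic_distances

    dmat, dm_labels = cophenetic_distances(tree)
    order = [dm_labels.index(s) for s in labels]
    d = dmat[np.ix_(order, order)]
    depth = d.max() / 2.0
    cov = depth - d / 2.0
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(labels)))
    a = chol @ rng.standard_normal(len(labels))
    return (a - a.mean()) / a.std()


def _env_layer(dem: DemGrid, which: str) -> np.ndarray:
    from phylograin import terrain

    if which == "elevation":
        layer = dem.values
    elif which == "tpi":
        layer = terrain.tpi(dem)
    else:  # flowdir: wetness proxy = log-accumulation
        _, accum = terrain.flow_direction(dem)
        layer = np.log10(1.0 + accum)
    sd = layer.std()
    return (layer - layer.mean()) / sd if sd > 0 else np.zeros_like(layer)


def _positions_in_cells(cells: np.ndarray, dem: DemGrid,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    iy, ix = np.unravel_index(cells, dem.values.shape)
    x = dem.xll + (ix + rng.uniform(size=len(cells))) * dem.cellsize
    y = dem.yll + (iy + rng.uniform(size=len(cells))) * dem.cellsize
    return x, y


def simulate_stem_map(
    tree: dendropy.Tree,
    dem: DemGrid,
    n_stems: int,
    dbh: DbhModel | None = None,
    scenario: AssemblyScenario | None = None,
) -> pd.DataFrame:
    """Stem census table under a chosen assembly scenario.

    Returns a validated stem table (stem_id, x, y, species, dbh_cm) with
    continuous coordinates inside the square plot covered by the DEM.
    """
    if n_stems < 1:
        raise ValueError("n_stems must be >= 1")
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 tips")
    dbh = dbh or DbhModel()
    scenario = scenario or AssemblyScenario()
    side = min(dem.ncols, dem.nrows) * dem.cellsize
    rng = np.random.default_rng(scenario.seed)
    abund = _rank_abundance(len(labels), rng)
    species_idx = rng.choice(len(labels), size=n_stems, p=abund)

    mode = scenario.mode if scenario.intensity > 0 else AssemblyMode.NEUTRAL
    if mode is AssemblyMode.NEUTRAL:
        x = rng.uniform(0, side, n_stems)
        y = rng.uniform(0, side, n_stems)
    elif mode is AssemblyMode.FILTERING:
        x, y = _place_filtering(species_idx, tree, labels, dem, scenario, rng)
    else:
        species_idx, x, y = _place_repulsion(
            species_idx, tree, labels, side, scenario, rng, abund=abund
        )

    dbh_cm = dbh.sample(n_stems, rng)
    width = len(str(n_stems))
    return pd.DataFrame(
        {
            "stem_id": [f"s{i:0{width}d}" for i in range(1, n_stems + 1)],
            "x": np.clip(x, 0, np.nextafter(side, 0)),
            "y": np.clip(y, 0, np.nextafter(side, 0)),
            "species": [labels[i] for i in species_idx],
            "dbh_cm": dbh_cm,
        }
    )


def _place_filtering(species_idx, tree, labels, dem, scenario, rng):
    """Cells weighted exp(intensity * affinity_s * env_c): conserved sorting."""
    affinity = _brownian_affinity(tree, labels, rng)
    env = _env_layer(dem, scenario.env_covariate).ravel()
    cells = np.empty(len(species_idx), dtype=int)
    for s in np.unique(species_idx):
        sel = species_idx == s
        logw = scenario.intensity * affinity[s] * env
        w = np.exp(logw - logw.max())
        w /= w.sum()
        cells[sel] = rng.choice(env.size, size=int(sel.sum()), p=w)
    x, y = _positions_in_cells(cells, dem, rng)
    return x, y


def _place_repulsion(species_idx, tree, labels, side, scenario, rng,
                     abund: np.ndarray | None = None):
    """Sequential placement penalizing phylogenetically close neighbors.

    Stem locations are uniform (overall density is neutral); the species
    of each stem is then assigned sequentially by a softmax over the pool,

        P(s) ∝ abundance_s * exp(-intensity * mean_j w_sj),

    where the mean runs over the established neighbors j within 10 m and
    w = 1 - (cophenetic distance / tree diameter) in [0, 1].  Species
    with close relatives already in the neighborhood are suppressed, so
    co-occurring species end up more distantly related than a random
    draw.  Conditioning the species label (rather than rejecting
    locations) keeps the penalty discriminative at any stem density.
    """
    from phylograin.phylo import cophenetic_distances

    dmat, dm_labels = cophenetic_distances(tree)
    order = [dm_labels.index(s) for s in labels]
    d = dmat[np.ix_(order, order)]
    w = 1.0 - d / d.max()
    n = len(species_idx)
    if abund is None:
        abund = np.full(len(labels), 1.0 / len(labels))
    log_abund = np.log(abund)

    xs = rng.uniform(0, side, n)
    ys = rng.uniform(0, side, n)
    r = REPULSION_RADIUS_M
    bins: dict[tuple[int, int], list[int]] = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        cx, cy = xs[i], ys[i]
        bx, by = int(cx / r), int(cy / r)
        nb: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                idx = bins.get((bx + dx, by + dy))
                if idx:
                    nb.extend(idx)
        logits = log_abund.copy()
        if nb:
            nb_arr = np.asarray(nb)
            dist2 = (xs[nb_arr] - cx) ** 2 + (ys[nb_arr] - cy) ** 2
            close = nb_arr[dist2 <= r * r]
            if close.size:
                logits = logits - scenario.intensity * w[:, out[close]].mean(axis=1)
        p = np.exp(logits - logits.max())
        p /= p.sum()
        out[i] = rng.choice(len(labels), p=p)
        bins.setdefault((bx, by), []).append(i)
    return out, xs, ys


# ---------------------------------------------------------------------------
# Regression fixture
# ---------------------------------------------------------------------------

def simulate_regression_dataset(
    beta: np.ndarray | list[float],
    noise_sd: float,
    n_groups: int,
    group_sd: float,
    n_per_group: int,
    seed: int,
) -> pd.DataFrame:
    """Mixed-model fixture with known coefficients.

    ``beta`` holds the intercept followed by the eight standardized
    predictors of the NRI/NTI model design (CI, elevation, aspect, slope,
    TPI, TRI, flow direction, SR).  Predictors are i.i.d. N(0, 1); the
    response adds a per-group random intercept (sd ``group_sd``) and
    residual noise (sd ``noise_sd``).  The response column is ``nri``.
    """
    from phylograin.models import EQ3_PREDICTORS

    beta = np.asarray(beta, dtype=float)
    if beta.shape != (1 + len(EQ3_PREDICTORS),):
        raise ValueError(
            f"beta must have length {1 + len(EQ3_PREDICTORS)} "
            f"(intercept + {EQ3_PREDICTORS})"
        )
    rng = np.random.default_rng(seed)
    n = n_groups * n_per_group
    X = rng.standard_normal((n, len(EQ3_PREDICTORS)))
    groups = np.repeat(np.arange(n_groups), n_per_group)
    intercepts = rng.normal(0.0, group_sd, n_groups)
    y = beta[0] + X @ beta[1:] + intercepts[groups] + rng.normal(0.0, noise_sd, n)
    frame = pd.DataFrame(X, columns=EQ3_PREDICTORS)
    frame["group"] = [f"g{g:03d}" for g in groups]
    frame["nri"] = y
    return frame
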