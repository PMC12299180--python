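"""Readers, writers and tiling for the three standard plot inputs.

A stem census is a delimited table (one row per stem: coordinates in
metres from the southwest plot corner, species code, DBH in cm), the
phylogeny is a rooted Newick tree with branch lengths whose tips are the
species codes, and the elevation model is an ESRI ASCII grid.  This module
validates those inputs, tiles the plot into nested quadrat grids
(2.5 / 5 / 10 m, nested inside the 20 m census blocks), classifies stems
into DBH-based life stages, and builds quadrat x species community
matrices.
"""

from __future__ import annotations

import enum
import io as _io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

#: Columns a stem table must carry.
STEM_COLUMNS = ("stem_id", "x", "y", "species", "dbh_cm")

#: Census floor: only stems with DBH strictly above 1 cm are recorded.
DBH_FLOOR_CM = 1.0

#: DBH (cm) thresholds splitting sapling / juvenile / adult.
SAPLING_MAX_DBH = 5.0
JUVENILE_MAX_DBH = 15.0


class StemTableError(ValueError):
    """A stem table failed validation; the message names the offending rows."""


class LifeStage(str, enum.Enum):
    """DBH-based life-history stage of a stem.

    sapling: DBH < 5 cm; juvenile: 5 <= DBH < 15 cm; adult: DBH >= 15 cm.
    """

    SAPLING = "sapling"
    JUVENILE = "juvenile"
    ADULT = "adult"


def classify_life_stage(dbh_cm: float) -> LifeStage:
    """Classify a single stem into its life stage from DBH in cm.

    Raises ValueError below the 1 cm census floor.  Boundaries follow the
    census convention: 5 cm is juvenile, 15 cm is adult.
    """
    if not np.isfinite(dbh_cm) or dbh_cm <= DBH_FLOOR_CM:
        raise ValueError(
            f"dbh={dbh_cm!r} cm is at or below the {DBH_FLOOR_CM} cm census floor"
        )
    if dbh_cm < SAPLING_MAX_DBH:
        return LifeStage.SAPLING
    if dbh_cm < JUVENILE_MAX_DBH:
        return LifeStage.JUVENILE
    return LifeStage.ADULT


def life_stages(dbh_cm: np.ndarray | pd.Series) -> pd.Series:
    """Vectorized stage classification; raises on any DBH at/below the floor."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(~np.isfinite(dbh) | (dbh <= DBH_FLOOR_CM)):
        bad = np.flatnonzero(~np.isfinite(dbh) | (dbh <= DBH_FLOOR_CM))[:5]
        raise ValueError(
            f"DBH at or below the {DBH_FLOOR_CM} cm census floor at rows {bad.tolist()}"
        )
    out = np.where(
        dbh < SAPLING_MAX_DBH,
        LifeStage.SAPLING.value,
        np.where(dbh < JUVENILE_MAX_DBH, LifeStage.JUVENILE.value, LifeStage.ADULT.value),
    )
    return pd.Series(out, index=getattr(dbh_cm, "index", None))


# ---------------------------------------------------------------------------
# Stem tables
# ---------------------------------------------------------------------------

def validate_stem_table(table: pd.DataFrame, plot_side: float | None = None) -> pd.DataFrame:
    """Validate a stem table in place and return it.

    Checks the required columns, numeric coordinates and DBH, the 1 cm
    census floor, non-empty species codes, and (when ``plot_side`` is
    given) that coordinates fall inside ``[0, plot_side]``.
    """
    missing = [c for c in STEM_COLUMNS if c not in table.columns]
    if missing:
        raise StemTableError(f"stem table missing columns: {missing}")
    for col in ("x", "y", "dbh_cm"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()]
        if len(bad):
            raise StemTableError(f"non-numeric {col!r} at rows {list(bad[:5])}")
        table[col] = vals.astype(float)
    low = table.index[table["dbh_cm"] <= DBH_FLOOR_CM]
    if len(low):
        raise StemTableError(
            f"DBH at or below the {DBH_FLOOR_CM} cm census floor at rows {list(low[:5])}"
        )
    empty = table.index[table["species"].astype(str).str.len() == 0]
    if len(empty):
        raise StemTableError(f"empty species code at rows {list(empty[:5])}")
    if plot_side is not None:
        out = table.index[
            (table["x"] < 0) | (table["x"] > plot_side)
            | (table["y"] < 0) | (table["y"] > plot_side)
        ]
        if len(out):
            raise StemTableError(
                f"coordinates outside [0, {plot_side}] m at rows {list(out[:5])}"
            )
    return table


def read_stem_table(path, plot_side: float | None = None) -> pd.DataFrame:
    """Read and validate a stem census CSV (columns stem_id,x,y,species,dbh_cm)."""
    table = pd.read_csv(path, dtype={"stem_id": str, "species": str})
    return validate_stem_table(table, plot_side=plot_side)


def write_stem_table(table: pd.DataFrame, path) -> None:
    """Write a stem table as CSV; round-trips through :func:`read_stem_table`."""
    table.loc[:, list(STEM_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Quadrat grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratGrid:
    """A square plot tiled into square quadrats of one spatial grain.

    Cells are half-open ``[i*scale, (i+1)*scale)`` in both axes; stems on
    the far plot boundary fold into the last cell so the tiling is a
    partition.  Quadrat ids are row-major: ``floor(y/s) * (side/s) + floor(x/s)``.
    """

    side: float
    scale: float

    def __post_init__(self) -> None:
        n = self.side / self.scale
        if abs(n - round(n)) > 1e-9 or self.scale <= 0:
            raise ValueError(
                f"plot side {self.side} m is not divisible by scale {self.scale} m"
            )

    @property
    def n_per_side(self) -> int:
        return int(round(self.side / self.scale))

    @property
    def n_quadrats(self) -> int:
        return self.n_per_side ** 2

    def assign(self, x, y) -> np.ndarray:
        """Row-major quadrat id for coordinate arrays inside the plot."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any((x < 0) | (x > self.side) | (y < 0) | (y > self.side)):
            raise ValueError("coordinates outside the plot")
        n = self.n_per_side
        col = np.minimum((x / self.scale).astype(int), n - 1)
        row = np.minimum((y / self.scale).astype(int), n - 1)
        return row * n + col

    def parent_ids(self, parent: "QuadratGrid") -> np.ndarray:
        """For each quadrat here, the id of the enclosing quadrat of a coarser grid."""
        if parent.side != self.side or parent.scale < self.scale:
            raise ValueError("parent grid must share the plot side and be coarser")
        n = self.n_per_side
        ids = np.arange(self.n_quadrats)
        row, col = ids // n, ids % n
        factor = parent.scale / self.scale
        return (row // factor).astype(int) * parent.n_per_side + (col // factor).astype(int)


def assign_quadrats(table: pd.DataFrame, grid: QuadratGrid) -> pd.Series:
    """Quadrat id per stem under the grid's half-open convention."""
    return pd.Series(grid.assign(table["x"].to_numpy(), table["y"].to_numpy()),
                     index=table.index, name=f"quadrat_{grid.scale}")


# ---------------------------------------------------------------------------
# Community matrices
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Quadrat x species stem counts at one spatial grain and stage filter.

    ``counts`` has one row per quadrat (all quadrats of the grid, including
    empty ones) and one column per species present after the stage filter.
    """

    counts: pd.DataFrame
    scale: float
    stage: LifeStage | None = None

    @property
    def empty_quadrats(self) -> np.ndarray:
        """Ids of quadrats with no stems after filtering (kept, but flagged)."""
        return self.counts.index[self.counts.sum(axis=1) == 0].to_numpy()

    @property
    def richness(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)


def build_community_matrix(
    table: pd.DataFrame,
    grid: QuadratGrid,
    stage: LifeStage | str | None = None,
) -> CommunityMatrix:
    """Count stems per quadrat and species, optionally restricted to one stage.

    Empty quadrats are retained as all-zero rows; the column set is the
    species actually present after filtering, so row sums conserve the
    filtered stem count.
    """
    sub = table
    if stage is not None:
        stage = LifeStage(stage)
        sub = table[life_stages(table["dbh_cm"]) == stage.value]
    ids = assign_quadrats(sub, grid) if len(sub) else pd.Series([], dtype=int)
    counts = (
        pd.crosstab(ids, sub["species"])
        .reindex(range(grid.n_quadrats), fill_value=0)
        .astype(int)
    )
    counts.index.name = "quadrat"
    counts.columns.name = "species"
    return CommunityMatrix(counts=counts, scale=grid.scale, stage=stage)


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------

def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Accepts a filesystem path or a Newick string.
    """
    s = str(path_or_string)
    if s.strip().startswith("("):
        tree = dendropy.Tree.get(data=s, schema="newick")
    else:
        tree = dendropy.Tree.get(path=s, schema="newick")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise ValueError("tree has an edge without a branch length")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_species(tree: dendropy.Tree, species: set[str] | list[str]) -> dendropy.Tree:
    """Prune a phylogeny down to a species checklist.

    The retained tips keep their root-to-tip path lengths: unifurcations
    created by pruning are collapsed with branch lengths summed, and a
    root left with a single child keeps that stem edge.  Species absent
    from the tree raise a ValueError listing the missing codes.
    """
    wanted = set(map(str, species))
    have = set(tip_labels(tree))
    missing = sorted(wanted - have)
    if missing:
        raise ValueError(f"species not found in tree: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(wanted))
    # retain_taxa suppresses internal unifurcations; ensure a unifurcate root
    # keeps its child edge so tip->root depths survive for retained tips.
    pruned.is_rooted = True
    return pruned


# ---------------------------------------------------------------------------
# Elevation rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

@dataclass
class DemGrid:
    """A regular elevation raster over the plot.

    ``values[iy, ix]`` is the elevation of the cell whose *lower-left*
    corner is ``(xll + ix*cell, yll + iy*cell)``: row 0 is the southern
    edge.  (The ESRI ASCII format stores rows north-to-south; the reader
    and writer flip accordingly.)
    """

    values: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DEM values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, same shape as values."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def covers(self, side: float) -> bool:
        """Whether the raster extent covers the square plot [0, side]^2."""
        return (
            self.xll <= 0
            and self.yll <= 0
            and self.xll + self.ncols * self.cellsize >= side
            and self.yll + self.nrows * self.cellsize >= side
        )


def read_ascii_grid(path) -> DemGrid:
    """Read an ESRI ASCII grid (6-line header + row-major values)."""
    with open(path) as fh:
        text = fh.read()
    lines = text.strip().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key!r}")
    values = np.loadtxt(_io.StringIO("\n".join(lines[body_start:])))
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return DemGrid(
        values=values[::-1],  # file is north-to-south; store south-up
        cellsize=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: DemGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll}\n")
        fh.write(f"yllcorner {grid.yll}\n")
        fh.write(f"cellsize {grid.cellsize}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        for row in grid.values[::-1]:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")
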