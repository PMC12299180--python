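"""Terrain derivatives from the plot DEM, aggregated to quadrat covariates.

Layers follow the usual moving-window definitions on a regular grid:
slope and aspect by Horn's 8-neighbor finite differences, the terrain
position index (TPI) as focal elevation minus the mean of the 8
neighbors, the terrain ruggedness index (TRI) as the standard deviation
of the 8 neighboring elevations, roughness as the 3x3 elevation range,
and D8 steepest-descent flow direction with topological flow
accumulation.  Aspect is folded to a bounded "southness" score in
[-1, 1] (due south = +1, due north = -1) so it can enter a linear model
without the 0/360-degree wrap problem.  Edge cells use the neighbors
that exist (no padding) for the windowed metrics; Horn derivatives use
nearest-edge replication.

Quadrat covariates are means of the cell values whose centers fall in
each quadrat; the flow-direction covariate is the mean of
log10(1 + flow accumulation), an ordinal wetness proxy, rather than the
categorical D8 code.  All covariates are z-scored per spatial grain
before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from phylograin.forest_io import DemGrid, QuadratGrid

#: D8 codes (ESRI convention) keyed by (d_row, d_col) with row 0 = south,
#: so +1 row is a step north.  E=1, SE=2, S=4, SW=8, W=16, NW=32, N=64, NE=128.
D8_OFFSETS = {
    (0, 1): 1,     # E
    (-1, 1): 2,    # SE
    (-1, 0): 4,    # S
    (-1, -1): 8,   # SW
    (0, -1): 16,   # W
    (1, -1): 32,   # NW
    (1, 0): 64,    # N
    (1, 1): 128,   # NE
}

#: Per-quadrat covariate column names in model order.
TERRAIN_COVARIATES = ("elevation", "slope", "aspect", "tpi", "tri", "roughness", "flowdir")


def _masked(dem: DemGrid) -> np.ndarray:
    z = dem.values.astype(float).copy()
    z[z == dem.nodata] = np.nan
    return z


def _require_window(dem: DemGrid) -> None:
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("windowed terrain metrics need at least a 3x3 grid")


def _neighbor_stack(z: np.ndarray, include_center: bool = False) -> np.ndarray:
    """Stack of 3x3-window values per cell; out-of-grid entries are NaN."""
    nr, nc = z.shape
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if include_center or (dr, dc) != (0, 0)]
    out = np.full((len(offsets), nr, nc), np.nan)
    for k, (dr, dc) in enumerate(offsets):
        src_r = slice(max(0, -dr), nr - max(0, dr))
        src_c = slice(max(0, -dc), nc - max(0, dc))
        dst_r = slice(max(0, dr), nr - max(0, -dr))
        dst_c = slice(max(0, dc), nc - max(0, -dc))
        out[k][dst_r, dst_c] = z[src_r, src_c]
    return out


def slope_aspect(dem: DemGrid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and southness aspect score by Horn's method.

    The gradient uses Horn's 8-neighbor weights with nearest-edge
    replication; the aspect score is -cos(downslope compass bearing), so
    a plane dipping due south scores +1 and due north -1.  Flat cells
    score 0.
    """
    _require_window(dem)
    z = np.pad(_masked(dem), 1, mode="edge")
    c = dem.cellsize
    E, W = z[1:-1, 2:], z[1:-1, :-2]
    N, S = z[2:, 1:-1], z[:-2, 1:-1]
    NE, NW = z[2:, 2:], z[2:, :-2]
    SE, SW = z[:-2, 2:], z[:-2, :-2]
    dzdx = ((NE + 2 * E + SE) - (NW + 2 * W + SW)) / (8 * c)
    dzdy = ((NE + 2 * N + NW) - (SE + 2 * S + SW)) / (8 * c)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore"):
        bearing = np.arctan2(-dzdx, -dzdy)  # downslope bearing from north
        score = np.where(grad > 0, -np.cos(bearing), 0.0)
    score[np.isnan(grad)] = np.nan
    return slope, score


def tpi(dem: DemGrid) -> np.ndarray:
    """Terrain position index: focal elevation minus mean of 8 neighbors."""
    _require_window(dem)
    z = _masked(dem)
    nb = _neighbor_stack(z)
    return z - np.nanmean(nb, axis=0)


def tri(dem: DemGrid) -> np.ndarray:
    """Terrain ruggedness index: population SD of the 8 neighbor elevations."""
    _require_window(dem)
    nb = _neighbor_stack(_masked(dem))
    return np.nanstd(nb, axis=0, ddof=0)


def roughness(dem: DemGrid) -> np.ndarray:
    """Elevation range (max - min) over the full 3x3 window."""
    _require_window(dem)
    win = _neighbor_stack(_masked(dem), include_center=True)
    return np.nanmax(win, axis=0) - np.nanmin(win, axis=0)


def flow_direction(dem: DemGrid) -> tuple[np.ndarray, np.ndarray]:
    """D8 flow direction codes and cell-count flow accumulation.

    Each cell drains to its steepest-descent neighbor (drop divided by
    centre distance); ties take the lowest code, and flats or pits (no
    lower neighbor) get code 0 and terminate flow.  Accumulation counts
    the cells draining through each cell, the cell itself included, by
    pushing counts down the D8 graph in order of decreasing elevation
    (strict descent makes that a topological order).
    """
    _require_window(dem)
    z = _masked(dem)
    nr, nc = z.shape
    items = sorted(D8_OFFSETS.items(), key=lambda kv: kv[1])  # ascending code
    drops = np.full((len(items), nr, nc), -np.inf)
    for k, ((dr, dc), _code) in enumerate(items):
        dist = dem.cellsize * (np.sqrt(2.0) if dr and dc else 1.0)
        shifted = np.full((nr, nc), np.nan)
        src_r = slice(max(0, dr), nr - max(0, -dr))
        src_c = slice(max(0, dc), nc - max(0, -dc))
        dst_r = slice(max(0, -dr), nr - max(0, dr))
        dst_c = slice(max(0, -dc), nc - max(0, dc))
        shifted[dst_r, dst_c] = z[src_r, src_c]
        with np.errstate(invalid="ignore"):
            d = (z - shifted) / dist
        drops[k] = np.where(np.isnan(d), -np.inf, d)
    best = drops.argmax(axis=0)  # first (= lowest code) among ties
    maxdrop = drops.max(axis=0)
    codes = np.array([code for _off, code in items])
    flowdir = np.where(maxdrop > 0, codes[best], 0).astype(int)

    accum = np.ones((nr, nc))
    offsets = {code: off for off, code in D8_OFFSETS.items()}
    order = np.argsort(z, axis=None)[::-1]  # highest first
    rows, cols = np.unravel_index(order, z.shape)
    for r, c in zip(rows, cols):
        code = flowdir[r, c]
        if code:
            dr, dc = offsets[code]
            accum[r + dr, c + dc] += accum[r, c]
    return flowdir, accum


@dataclass
class TerrainLayers:
    """Per-cell terrain derivatives of one DEM."""

    dem: DemGrid
    elevation: np.ndarray
    slope: np.ndarray
    aspect: np.ndarray
    tpi: np.ndarray
    tri: np.ndarray
    roughness: np.ndarray
    flowdir_code: np.ndarray
    flow_accum: np.ndarray


def compute_terrain_layers(dem: DemGrid) -> TerrainLayers:
    s, a = slope_aspect(dem)
    fd, fa = flow_direction(dem)
    return TerrainLayers(
        dem=dem,
        elevation=_masked(dem),
        slope=s,
        aspect=a,
        tpi=tpi(dem),
        tri=tri(dem),
        roughness=roughness(dem),
        flowdir_code=fd,
        flow_accum=fa,
    )


def quadrat_terrain(layers: TerrainLayers, grid: QuadratGrid) -> pd.DataFrame:
    """Mean terrain covariates per quadrat (cell centers inside the quadrat).

    The ``flowdir`` covariate is the mean of log10(1 + flow accumulation),
    a monotone wetness proxy.  Quadrats finer than the DEM resolution
    (no cell center inside) take the value of the cell containing the
    quadrat center.  Raises if the DEM does not cover the plot.
    """
    dem = layers.dem
    if not dem.covers(grid.side):
        raise ValueError("DEM does not cover the plot extent")
    xg, yg = dem.cell_centers()
    inside = (xg >= 0) & (xg <= grid.side) & (yg >= 0) & (yg <= grid.side)
    ids = grid.assign(xg[inside], yg[inside])
    data = {
        "elevation": layers.elevation[inside],
        "slope": layers.slope[inside],
        "aspect": layers.aspect[inside],
        "tpi": layers.tpi[inside],
        "tri": layers.tri[inside],
        "roughness": layers.roughness[inside],
        "flowdir": np.log10(1.0 + layers.flow_accum[inside]),
    }
    frame = pd.DataFrame(data)
    frame["quadrat"] = ids
    out = frame.groupby("quadrat").mean().reindex(range(grid.n_quadrats))
    out.index.name = "quadrat"
    empty = out.index[out["elevation"].isna()].to_numpy()
    if len(empty):
        n = grid.n_per_side
        qx = (empty % n + 0.5) * grid.scale
        qy = (empty // n + 0.5) * grid.scale
        ix = np.clip(((qx - dem.xll) / dem.cellsize).astype(int), 0, dem.ncols - 1)
        iy = np.clip(((qy - dem.yll) / dem.cellsize).astype(int), 0, dem.nrows - 1)
        for col, layer in (
            ("elevation", layers.elevation), ("slope", layers.slope),
            ("aspect", layers.aspect), ("tpi", layers.tpi),
            ("tri", layers.tri), ("roughness", layers.roughness),
            ("flowdir", np.log10(1.0 + layers.flow_accum)),
        ):
            out.loc[empty, col] = layer[iy, ix]
    return out


def zscore(frame: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Standardize columns to mean 0, SD 1; zero variance is an error."""
    out = frame.copy()
    for col in columns or frame.columns:
        vals = out[col].to_numpy(dtype=float)
        sd = np.nanstd(vals)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot z-score column {col!r}: zero or undefined variance")
        out[col] = (vals - np.nanmean(vals)) / sd
    return out
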