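"""Hegyi neighborhood competition index.

For a focal tree i with DBH d_i, CI_i = sum_j (d_j / d_i) / dist_ij over
all neighbors j within the chosen radius — a size-ratio, distance-decayed
crowding measure.  All stems of every species and stage compete; focal
stems are stage-filtered only when aggregating to quadrats.  Coincident
stems (zero distance) are a data defect and raise rather than being
clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from phylograin.forest_io import LifeStage, QuadratGrid, life_stages


def hegyi_ci(table: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Per-stem Hegyi competition index within a circular neighborhood.

    Neighbor search uses a KD-tree, so cost is near-linear in stem count.
    Returns a frame (stem_id, scale, CI, n_competitors) aligned with the
    input rows; isolated stems get CI 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dbh = table["dbh_cm"].to_numpy(dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("all stems need positive DBH")
    xy = table[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    ci = np.zeros(len(table))
    ncomp = np.zeros(len(table), dtype=int)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dist = np.hypot(*(xy[i] - xy[j]).T)
        zero = dist == 0
        if zero.any():
            a, b = pairs[zero][0]
            raise ValueError(
                f"coincident stems {table['stem_id'].iloc[a]!r} and "
                f"{table['stem_id'].iloc[b]!r} (distance 0)"
            )
        np.add.at(ci, i, (dbh[j] / dbh[i]) / dist)
        np.add.at(ci, j, (dbh[i] / dbh[j]) / dist)
        np.add.at(ncomp, i, 1)
        np.add.at(ncomp, j, 1)
    return pd.DataFrame(
        {
            "stem_id": table["stem_id"].to_numpy(),
            "scale": radius,
            "CI": ci,
            "n_competitors": ncomp,
        },
        index=table.index,
    )


def hegyi_ci_same_quadrat(table: pd.DataFrame, grid: QuadratGrid) -> pd.DataFrame:
    """Hegyi CI restricted to competitors sharing the focal stem's quadrat.

    Alternative neighborhood reading: competitors are the other stems of
    the same quadrat instead of a circular radius (which avoids cross-
    quadrat neighbors but introduces edge artifacts at quadrat borders).
    """
    xy = table[["x", "y"]].to_numpy(dtype=float)
    dbh = table["dbh_cm"].to_numpy(dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("all stems need positive DBH")
    ids = grid.assign(xy[:, 0], xy[:, 1])
    ci = np.zeros(len(table))
    ncomp = np.zeros(len(table), dtype=int)
    for _q, idx in pd.Series(np.arange(len(table))).groupby(ids):
        idx = idx.to_numpy()
        if len(idx) < 2:
            continue
        d = np.hypot(
            xy[idx, 0][:, None] - xy[idx, 0][None, :],
            xy[idx, 1][:, None] - xy[idx, 1][None, :],
        )
        off = ~np.eye(len(idx), dtype=bool)
        if np.any(d[off] == 0):
            a, b = np.argwhere((d == 0) & off)[0]
            raise ValueError(
                f"coincident stems {table['stem_id'].iloc[idx[a]]!r} and "
                f"{table['stem_id'].iloc[idx[b]]!r} (distance 0)"
            )
        with np.errstate(divide="ignore"):
            contrib = (dbh[idx][None, :] / dbh[idx][:, None]) / d
        contrib[~off] = 0.0
        ci[idx] = contrib.sum(axis=1)
        ncomp[idx] = len(idx) - 1
    return pd.DataFrame(
        {
            "stem_id": table["stem_id"].to_numpy(),
            "scale": grid.scale,
            "CI": ci,
            "n_competitors": ncomp,
        },
        index=table.index,
    )


def quadrat_ci(
    records: pd.DataFrame,
    table: pd.DataFrame,
    grid: QuadratGrid,
    stage: LifeStage | str | None = None,
) -> pd.Series:
    """Mean CI over focal stems of one stage per quadrat.

    ``records`` must come from :func:`hegyi_ci` on the same table (rows
    aligned).  Quadrats without any focal stem of the requested stage are
    NaN (flagged missing), not zero.
    """
    if len(records) != len(table):
        raise ValueError("records and stem table must be row-aligned")
    mask = np.ones(len(table), dtype=bool)
    if stage is not None:
        stage = LifeStage(stage)
        mask = (life_stages(table["dbh_cm"]) == stage.value).to_numpy()
    ids = grid.assign(table["x"].to_numpy()[mask], table["y"].to_numpy()[mask])
    means = (
        pd.Series(records["CI"].to_numpy()[mask])
        .groupby(ids).mean()
        .reindex(range(grid.n_quadrats))
    )
    means.index.name = "quadrat"
    means.name = "ci"
    return means
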