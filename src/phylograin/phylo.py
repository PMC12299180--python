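"""Per-quadrat phylogenetic structure: SR, Faith's PD, MPD/MNTD, NRI/NTI.

The net relatedness index (NRI) and nearest taxon index (NTI) are negated
standardized effect sizes of the mean pairwise distance (MPD) and mean
nearest-taxon distance (MNTD) against a taxa-label randomization null:

    NRI = -(MPD_obs - mean MPD_null) / sd MPD_null

so phylogenetic clustering is positive and overdispersion negative.  The
null shuffles tip labels on the cophenetic distance matrix while holding
each quadrat's observed richness and occupancy fixed; because the null
MPD/MNTD distribution of a community then depends only on its richness,
it is computed once per richness class as uniform random subsets of the
species pool (all species present in the community matrix at that grain
and stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from phylograin.forest_io import CommunityMatrix


def cophenetic_distances(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip patristic distance matrix, rows/cols sorted by tip label."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dmat = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for t1, t2 in pdm.distinct_taxon_pair_iter():
        d = pdm.patristic_distance(t1, t2)
        i, j = idx[t1.label], idx[t2.label]
        dmat[i, j] = dmat[j, i] = d
    return dmat, labels


def _tip_edge_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Edge lengths and, per tip, the boolean set of edges on its root path.

    Lets Faith's PD for any community be computed as the total length of
    the union of tip->root edge sets (root-inclusive).
    """
    edges = []
    edge_id: dict[int, int] = {}
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge_id[id(edge)] = len(edges)
            edges.append(edge.length)
    lengths = np.asarray(edges)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    lab_i = {lab: i for i, lab in enumerate(labels)}
    paths = np.zeros((len(labels), len(lengths)), dtype=bool)
    for leaf in tree.leaf_node_iter():
        node = leaf
        while node is not None:
            eid = edge_id.get(id(node.edge))
            if eid is not None:
                paths[lab_i[leaf.taxon.label], eid] = True
            node = node.parent_node
    return labels, lengths, paths


def faith_pd(species, tree: dendropy.Tree) -> float:
    """Faith's phylogenetic diversity of a set of species codes.

    Root-inclusive: the sum of branch lengths of the minimal subtree
    spanning the species and the tree root, so a single species has
    PD > 0 and the full tip set recovers the total tree length.  An
    empty community has PD 0.
    """
    species = set(map(str, species))
    if not species:
        return 0.0
    labels, lengths, paths = _tip_edge_matrix(tree)
    missing = species - set(labels)
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    mask = np.array([lab in species for lab in labels])
    return float(lengths[paths[mask].any(axis=0)].sum())


def mpd(dmat: np.ndarray, present) -> float:
    """Mean pairwise distance over unordered distinct pairs of present species.

    ``present`` is a boolean mask or index array over the matrix order.
    NaN when fewer than two species are present.
    """
    idx = _as_indices(present, dmat.shape[0])
    k = len(idx)
    if k < 2:
        return float("nan")
    sub = dmat[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mntd(dmat: np.ndarray, present) -> float:
    """Mean distance from each present species to its nearest present relative."""
    idx = _as_indices(present, dmat.shape[0])
    k = len(idx)
    if k < 2:
        return float("nan")
    sub = dmat[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _as_indices(present, n: int) -> np.ndarray:
    present = np.asarray(present)
    if present.dtype == bool:
        if present.shape != (n,):
            raise ValueError("presence mask length does not match the matrix")
        return np.flatnonzero(present)
    return present.astype(int)


@dataclass(frozen=True)
class NullModelConfig:
    """Randomization null for the standardized effect sizes.

    ``taxa_shuffle`` permutes tip labels on the distance matrix;
    ``n_rand`` draws (default 999) per richness class; fully seeded.
    """

    method: str = "taxa_shuffle"
    n_rand: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method != "taxa_shuffle":
            raise ValueError(f"unknown null model {self.method!r}")
        if self.n_rand < 99:
            raise ValueError("n_rand must be >= 99 for reportable effect sizes")


def _null_table(dmat: np.ndarray, richness: np.ndarray, cfg: NullModelConfig
                ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Null MPD and MNTD samples per distinct richness class."""
    rng = np.random.default_rng(cfg.seed)
    S = dmat.shape[0]
    table: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in sorted(set(int(k) for k in richness if k >= 2)):
        mpd_s = np.empty(cfg.n_rand)
        mntd_s = np.empty(cfg.n_rand)
        for r in range(cfg.n_rand):
            idx = rng.permutation(S)[:k]
            sub = dmat[np.ix_(idx, idx)]
            mpd_s[r] = sub.sum() / (k * (k - 1))
            np.fill_diagonal(sub, np.inf)
            mntd_s[r] = sub.min(axis=1).mean()
        table[k] = (mpd_s, mntd_s)
    return table


def _rank_p(obs: float, null: np.ndarray) -> float:
    """Two-sided randomization p from the observed value's rank in the null."""
    n = len(null)
    lo = (np.sum(null <= obs) + 1) / (n + 1)
    hi = (np.sum(null >= obs) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def ses_metrics(
    cm: CommunityMatrix,
    tree: dendropy.Tree,
    cfg: NullModelConfig | None = None,
) -> pd.DataFrame:
    """SR, PD, MPD, MNTD and null-standardized NRI/NTI per quadrat.

    The species pool is the full column set of the community matrix.
    Quadrats with fewer than two species, or whose null SD is zero (e.g.
    a community equal to the whole pool), carry NaN NRI/NTI and
    ``valid = False``; they are retained in the table.  Same config seed
    gives bit-identical output.
    """
    cfg = cfg or NullModelConfig()
    pool = [str(c) for c in cm.counts.columns]
    dmat_full, labels = cophenetic_distances(tree)
    missing = set(pool) - set(labels)
    if missing:
        raise ValueError(f"matrix species not in tree: {sorted(missing)}")
    order = [labels.index(s) for s in pool]
    dmat = dmat_full[np.ix_(order, order)]

    presence = cm.counts.to_numpy() > 0
    richness = presence.sum(axis=1)
    nulls = _null_table(dmat, richness, cfg)

    # Faith's PD, vectorized over quadrats via tip->root edge sets.
    tip_labels, lengths, paths = _tip_edge_matrix(tree)
    tip_order = [tip_labels.index(s) for s in pool]
    pool_paths = paths[tip_order]
    pd_vals = ((presence.astype(float) @ pool_paths) > 0) @ lengths
    pd_vals[richness == 0] = 0.0

    rows = []
    for q in range(presence.shape[0]):
        k = int(richness[q])
        obs_mpd = mpd(dmat, presence[q]) if k >= 2 else np.nan
        obs_mntd = mntd(dmat, presence[q]) if k >= 2 else np.nan
        rec = {
            "quadrat": cm.counts.index[q],
            "SR": k,
            "PD": pd_vals[q],
            "MPD": obs_mpd,
            "MNTD": obs_mntd,
            "mpd_null_mean": np.nan, "mpd_null_sd": np.nan,
            "mntd_null_mean": np.nan, "mntd_null_sd": np.nan,
            "NRI": np.nan, "NTI": np.nan,
            "p_mpd": np.nan, "p_mntd": np.nan,
            "valid": False,
        }
        if k >= 2:
            mpd_s, mntd_s = nulls[k]
            m_mean, m_sd = mpd_s.mean(), mpd_s.std(ddof=0)
            t_mean, t_sd = mntd_s.mean(), mntd_s.std(ddof=0)
            rec.update(mpd_null_mean=m_mean, mpd_null_sd=m_sd,
                       mntd_null_mean=t_mean, mntd_null_sd=t_sd)
            # relative floor guards degenerate classes (e.g. community = pool)
            # whose null sd is pure floating-point noise
            if m_sd > 1e-9 * m_mean and t_sd > 1e-9 * t_mean:
                rec.update(
                    NRI=-(obs_mpd - m_mean) / m_sd,
                    NTI=-(obs_mntd - t_mean) / t_sd,
                    p_mpd=_rank_p(obs_mpd, mpd_s),
                    p_mntd=_rank_p(obs_mntd, mntd_s),
                    valid=True,
                )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["scale"] = cm.scale
    out["stage"] = cm.stage.value if cm.stage is not None else "community"
    return out


def stage_summary(rows: pd.DataFrame, min_quadrats: int = 3) -> pd.DataFrame:
    """Mean NRI/NTI per (scale, stage) with a one-sample t-test against 0.

    The tabular analogue of a violin-plot panel grid: one row per
    scale x stage x metric with n, mean, SE, t and two-sided p.  Groups
    with fewer than ``min_quadrats`` valid quadrats are flagged and carry
    NaN statistics.
    """
    recs = []
    for (scale, stage), grp in rows.groupby(["scale", "stage"], sort=True):
        for metric in ("NRI", "NTI"):
            vals = grp.loc[grp["valid"], metric].dropna().to_numpy()
            rec = {"scale": scale, "stage": stage, "metric": metric,
                   "n": len(vals), "mean": np.nan, "se": np.nan,
                   "t": np.nan, "p": np.nan, "ok": len(vals) >= min_quadrats}
            if len(vals) >= min_quadrats:
                res = stats.ttest_1samp(vals, 0.0)
                rec.update(mean=vals.mean(),
                           se=vals.std(ddof=1) / np.sqrt(len(vals)),
                           t=float(res.statistic), p=float(res.pvalue))
            recs.append(rec)
    return pd.DataFrame(recs)
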