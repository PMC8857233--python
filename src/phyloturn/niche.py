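"""Phylogenetic niche conservatism checks.

Nearest-taxon null models are only meaningful when closely related taxa
occupy similar niches. This module estimates per-ASV niche optima from an
environmental table, computes standardized euclidean niche distances, and
runs a Mantel correlogram of niche distance against phylogenetic distance:
the prerequisite is a significant positive correlation (positive
autocorrelation) in the shortest phylogenetic distance classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["NicheProfile", "niche_optima", "niche_distance", "mantel_correlogram"]


@dataclass
class NicheProfile:
    """Per-ASV niche optima in native units plus a z-scored copy."""

    optima: pd.DataFrame
    standardized: pd.DataFrame


def niche_optima(matrix: pd.DataFrame, env_table: pd.DataFrame,
                 statistic: str = "mean") -> NicheProfile:
    """Abundance-weighted niche optima.

    The optimum of ASV i for variable E is sum_s(a_is * E_s) / sum_s(a_is)
    over samples. ``statistic="median"`` uses the abundance-weighted median
    instead. ASVs with zero total abundance are excluded.
    """
    env = env_table.loc[matrix.columns].astype(float)
    if env.isna().any().any():
        raise ValueError("environmental values missing for some samples")
    tot = matrix.sum(axis=1)
    keep = tot > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%d zero-abundance ASVs excluded from niche optima", dropped)
    A = matrix.loc[keep]
    if statistic == "mean":
        opt = (A.values @ env.values) / A.values.sum(axis=1, keepdims=True)
    elif statistic == "median":
        opt = np.empty((A.shape[0], env.shape[1]))
        for vi in range(env.shape[1]):
            e = env.values[:, vi]
            order = np.argsort(e)
            for ai in range(A.shape[0]):
                w = A.values[ai, order]
                cw = np.cumsum(w) / w.sum()
                opt[ai, vi] = e[order][np.searchsorted(cw, 0.5)]
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    opt = pd.DataFrame(opt, index=A.index, columns=env.columns)
    sd = opt.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        logger.warning("zero-variance niche variables dropped: %s", zero_var)
    kept = opt.drop(columns=zero_var)
    std = (kept - kept.mean()) / kept.std(ddof=1)
    return NicheProfile(optima=opt, standardized=std)


def niche_distance(profile: NicheProfile) -> pd.DataFrame:
    """Euclidean distance between ASVs on standardized niche optima."""
    std = profile.standardized
    if std.shape[1] == 0:
        raise ValueError("no informative niche variables")
    D = squareform(pdist(std.values, metric="euclidean"))
    return pd.DataFrame(D, index=std.index, columns=std.index)


def _condensed(square: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(square, k=1)
    return square[iu]


def mantel_correlogram(
    phylo_dist,
    niche_dist,
    n_classes: int | None = None,
    permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Mantel correlogram of niche distance across phylogenetic distance classes.

    Classes partition the observed phylogenetic distance range (Sturges' rule
    on the pair count by default). Per class, the Mantel statistic is the
    Pearson correlation between the niche distances and the within-class
    indicator, sign-flipped so positive r means pairs in the class are more
    similar (positive autocorrelation). p-values come from joint row/column
    permutations of the niche matrix (two-sided) with progressive Holm
    correction across classes from short to long.

    Returns a DataFrame with columns class_min, class_max, midpoint, n_pairs,
    r, p, p_corrected, low_power.
    """
    rng = np.random.default_rng(rng)
    if hasattr(phylo_dist, "data"):
        p_ids = list(phylo_dist.ids)
        P = np.asarray(phylo_dist.data, float)
    else:
        p_ids = list(phylo_dist.index)
        P = phylo_dist.values.astype(float)
    if hasattr(niche_dist, "data"):
        n_ids = list(niche_dist.ids)
        Q = np.asarray(niche_dist.data, float)
    else:
        n_ids = list(niche_dist.index)
        Q = niche_dist.values.astype(float)
    shared = [i for i in p_ids if i in set(n_ids)]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared ids")
    P = P[np.ix_([p_ids.index(i) for i in shared], [p_ids.index(i) for i in shared])]
    Q = Q[np.ix_([n_ids.index(i) for i in shared], [n_ids.index(i) for i in shared])]

    p_cond = _condensed(P)
    n_pairs = p_cond.size
    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(n_pairs)))
    edges = np.linspace(p_cond.min(), p_cond.max(), n_classes + 1)
    label = np.clip(np.digitize(p_cond, edges[1:-1]), 0, n_classes - 1)

    n = len(shared)
    iu = np.triu_indices(n, k=1)
    q_cond = Q[iu]
    q_mean, q_sd = q_cond.mean(), q_cond.std()
    counts = np.bincount(label, minlength=n_classes).astype(float)

    def class_r(qc: np.ndarray) -> np.ndarray:
        # pearson(indicator_c, q), vectorized over classes via bincount
        sums = np.bincount(label, weights=qc, minlength=n_classes)
        frac = counts / n_pairs
        cov = sums / n_pairs - frac * qc.mean()
        sd_x = np.sqrt(frac * (1 - frac))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (sd_x * qc.std())
        return -r  # positive = within-class pairs more similar

    r_obs = class_r(q_cond)
    exceed = np.zeros(n_classes)
    for _ in range(permutations):
        perm = rng.permutation(n)
        q_perm = Q[np.ix_(perm, perm)][iu]
        exceed += np.abs(class_r(q_perm)) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1) / (permutations + 1)

    # progressive Holm correction, short classes first
    p_corr = np.empty(n_classes)
    running = 0.0
    for c in range(n_classes):
        running = max(running, min(1.0, p[c] * (c + 1)))
        p_corr[c] = running

    mid = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame(
        {
            "class_min": edges[:-1],
            "class_max": edges[1:],
            "midpoint": mid,
            "n_pairs": counts.astype(int),
            "r": r_obs,
            "p": p,
            "p_corrected": p_corr,
            "low_power": counts < 20,
        }
    )
    if out["low_power"].any():
        logger.info("%d distance classes have < 20 pairs", int(out["low_power"].sum()))
    return out
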