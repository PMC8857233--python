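"""Per-ASV, per-sample-pair phyloscore z-statistics against a random-membership null.

For an ASV *i* present in sample *j* and absent from sample *k*, the observed
statistic is the nearest patristic distance ``d`` from *i* to any ASV present
in *k*. The null draws random communities of the same richness ``N_k`` from
the taxon pool (all ASVs in the dataset except *i*) and records the nearest
distance to each. The phyloscore is

    z = (log d - mean(log d0_m)) / sd(log d0_m)

with the mean and sd taken over the ``M`` null nearest distances (natural
log, M = 100 by default). Negative z means *i* is replaced by closer
relatives across communities than expected by chance; a clade of
systematically negative z is the signature of homogeneous ecological
selection.

Implementation note: for a uniform random ``N``-subset of a pool of ``P``
candidate distances, the nearest distance is the pool's ``r``-th order
statistic with probability ``C(P-r, N-1) / C(P, N)``. Sampling that rank
directly is distributionally identical to drawing the subset and taking the
minimum, and makes both the Monte-Carlo draw O(P + M) and the exhaustive
(exact) null a closed form with no combinatorial enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "nearest_beta_distance",
    "null_nearest_distances",
    "exhaustive_null",
    "phyloscore",
    "all_phyloscores",
    "aggregate_phyloscores",
    "PhyloscoreRecord",
]

SUMMARY_METRICS = ("total", "mean", "median", "n_pairs", "mean_over_sd")


@dataclass
class PhyloscoreRecord:
    """One (ASV i, donor j, recipient k) phyloscore."""

    asv: str
    donor_sample: str
    recipient_sample: str
    d_obs: float
    null_mean_log: float
    null_sd_log: float
    z: float


def _presence(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix > 0


def _distance_floor(values: np.ndarray) -> float:
    """Half the smallest positive off-diagonal distance; log(0) guard."""
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("all patristic distances are zero")
    return 0.5 * float(pos.min())


def nearest_beta_distance(asv_i: str, sample_k: str, matrix: pd.DataFrame, dist) -> float:
    """Min patristic distance from ``asv_i`` to the ASVs present in ``sample_k``.

    ``asv_i`` must be absent from ``sample_k``.
    """
    pres = matrix[sample_k] > 0
    if pres.get(asv_i, False):
        raise ValueError(f"{asv_i} is present in {sample_k}")
    present = [a for a in matrix.index[pres] if a != asv_i]
    if not present:
        raise ValueError(f"sample {sample_k} is empty")
    row = dist[asv_i]
    idx = [dist.index(a) for a in present]
    return float(np.min(row[idx]))


def _min_rank_pmf(pool_size: int, n_k: int) -> np.ndarray:
    """P(min of a uniform N-subset is the pool's r-th smallest), r = 1..P.

    log C(P - r, N - 1) - log C(P, N), zero beyond r = P - N + 1.
    """
    P, N = pool_size, n_k
    if not 1 <= N <= P:
        raise ValueError(f"need 1 <= N_k ({N}) <= pool size ({P})")
    r = np.arange(1, P + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        logp = (
            gammaln(P - r + 1)
            - gammaln(N)
            - gammaln(P - r - N + 2)
            - (gammaln(P + 1) - gammaln(N + 1) - gammaln(P - N + 1))
        )
    pmf = np.zeros(P)
    valid = r <= P - N + 1
    pmf[valid] = np.exp(logp[valid])
    pmf /= pmf.sum()
    return pmf


def _sample_min_ranks(pmf: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(M), side="right")


def null_nearest_distances(
    asv_i: str,
    sample_k: str,
    matrix: pd.DataFrame,
    dist,
    M: int,
    rng: np.random.Generator,
    pool: list[str] | None = None,
) -> np.ndarray:
    """M null nearest distances for ``asv_i`` against random communities of
    the richness observed in ``sample_k``.

    Each value is the minimum distance from *i* to a uniform random
    ``N_k``-subset (without replacement) of the pool (all dataset ASVs except
    *i* by default).
    """
    n_k = int((matrix[sample_k] > 0).sum())
    if pool is None:
        pool = [a for a in matrix.index if a != asv_i]
    else:
        pool = [a for a in pool if a != asv_i]
    if n_k > len(pool):
        raise ValueError(f"richness N_k={n_k} exceeds pool size {len(pool)}")
    row = dist[asv_i]
    d = np.sort(row[[dist.index(a) for a in pool]])
    pmf = _min_rank_pmf(len(pool), n_k)
    ranks = _sample_min_ranks(pmf, M, rng)
    return d[ranks]


def exhaustive_null(
    asv_i: str,
    sample_k: str,
    matrix: pd.DataFrame,
    dist,
    pool: list[str] | None = None,
    floor: float | None = None,
) -> tuple[float, float]:
    """Exact mean and sd of the log null nearest distance over *all*
    ``N_k``-subsets of the pool, uniformly weighted.

    Computed from the order-statistic distribution of the minimum, so it is
    exact for any pool size (no enumeration).
    """
    n_k = int((matrix[sample_k] > 0).sum())
    if pool is None:
        pool = [a for a in matrix.index if a != asv_i]
    else:
        pool = [a for a in pool if a != asv_i]
    row = dist[asv_i]
    d = np.sort(row[[dist.index(a) for a in pool]])
    if floor is None:
        floor = _distance_floor(np.asarray(dist.data))
    logd = np.log(np.maximum(d, floor))
    pmf = _min_rank_pmf(len(pool), n_k)
    mean = float(pmf @ logd)
    var = float(pmf @ (logd - mean) ** 2)
    return mean, float(np.sqrt(max(var, 0.0)))


def phyloscore(
    asv_i: str,
    sample_j: str,
    sample_k: str,
    matrix: pd.DataFrame,
    dist,
    M: int = 100,
    rng: np.random.Generator | None = None,
    pool: list[str] | None = None,
) -> PhyloscoreRecord:
    """Phyloscore of ``asv_i`` for the ordered pair (donor j, recipient k)."""
    pres = _presence(matrix)
    if not pres.loc[asv_i, sample_j]:
        raise ValueError(f"{asv_i} not present in donor {sample_j}")
    if pres.loc[asv_i, sample_k]:
        raise ValueError(f"{asv_i} present in recipient {sample_k}")
    rng = np.random.default_rng(rng)
    floor = _distance_floor(np.asarray(dist.data))
    d_obs = max(nearest_beta_distance(asv_i, sample_k, matrix, dist), floor)
    null = np.maximum(null_nearest_distances(asv_i, sample_k, matrix, dist, M, rng, pool), floor)
    logn = np.log(null)
    m, s = float(logn.mean()), float(logn.std(ddof=1))
    z = (np.log(d_obs) - m) / s if s > 0 else np.nan
    return PhyloscoreRecord(asv_i, sample_j, sample_k, float(d_obs), m, s, float(z))


def all_phyloscores(
    matrix: pd.DataFrame,
    dist,
    M: int = 100,
    rng: np.random.Generator | int | None = None,
    pool: str = "regional",
    pair_filter=None,
    share_null_across_donors: bool = True,
) -> pd.DataFrame:
    """Phyloscore records for every (ASV, donor, recipient) with asymmetric
    presence, over all unordered sample pairs (both directions covered).

    Parameters
    ----------
    pool : {"regional", "pair"}
        Null taxon pool: every dataset ASV except the focal one (default,
        matching the tip-shuffle logic of the community framework), or only
        the taxa present in the union of the two compared samples.
    pair_filter : callable(sample_j, sample_k) -> bool, optional
        Restrict to pairs for which it returns True (e.g. within-group).
    share_null_across_donors : bool
        The observed statistic and the null depend only on (i, recipient k);
        by default one Monte-Carlo null per (i, k) is shared by every donor
        sample, which leaves each record's distribution unchanged.

    Returns
    -------
    DataFrame with columns asv, donor_sample, recipient_sample, d_obs,
    null_mean_log, null_sd_log, z. Records with a degenerate null
    (sd = 0) carry z = NaN and are excluded from aggregation.
    """
    rng = np.random.default_rng(rng)
    if pool not in ("regional", "pair"):
        raise ValueError("pool must be 'regional' or 'pair'")

    asvs = list(matrix.index)
    samples = list(matrix.columns)
    ids = list(dist.ids)
    if set(asvs) - set(ids):
        raise ValueError("matrix contains ASVs missing from the distance matrix")
    col = {a: ids.index(a) for a in asvs}
    D = np.asarray(dist.data)
    sub = D[np.ix_([col[a] for a in asvs], [col[a] for a in asvs])]
    floor = _distance_floor(D)
    logfloor = np.log(floor)

    P = (matrix.values > 0)
    n_asv, n_samp = P.shape
    richness = P.sum(axis=0)

    # sorted distance rows excluding self (regional pool = all ASVs minus focal)
    sub_noself = sub.copy()
    np.fill_diagonal(sub_noself, np.inf)
    sorted_d = np.sort(sub_noself, axis=1)[:, :-1]

    rec_asv, rec_j, rec_k = [], [], []
    rec_d, rec_m, rec_s, rec_z = [], [], [], []
    n_floored = 0

    pmf_cache: dict[int, np.ndarray] = {}

    def pmf_for(pool_size: int, n_k: int) -> np.ndarray:
        key = pool_size * (n_asv + 1) + n_k
        if key not in pmf_cache:
            pmf_cache[key] = _min_rank_pmf(pool_size, n_k)
        return pmf_cache[key]

    for k_idx, k in enumerate(samples):
        present = P[:, k_idx]
        n_k = int(richness[k_idx])
        if n_k == 0:
            logger.warning("sample %s is empty; skipped as recipient", k)
            continue
        absent = np.where(~present & P.any(axis=1))[0]
        if absent.size == 0:
            continue
        # observed nearest distances for every absent focal ASV at once
        d_obs_all = sub[np.ix_(absent, np.where(present)[0])].min(axis=1)
        for i_pos, i_idx in enumerate(absent):
            donors = [
                samples[j_idx]
                for j_idx in np.where(P[i_idx])[0]
                if pair_filter is None or pair_filter(samples[j_idx], k)
            ]
            if not donors:
                continue
            d_obs = d_obs_all[i_pos]
            if d_obs < floor:
                n_floored += 1
                d_obs = floor
            log_dobs = np.log(d_obs)

            if pool == "regional":
                d_sorted = sorted_d[i_idx]
                pmf = pmf_for(n_asv - 1, n_k)
                logd = np.log(np.maximum(d_sorted, floor))
                if share_null_across_donors:
                    ranks = _sample_min_ranks(pmf, M, rng)
                    logn = logd[ranks]
                    m, s = float(logn.mean()), float(logn.std(ddof=1))
                    z = (log_dobs - m) / s if s > 0 else np.nan
                    for j in donors:
                        rec_asv.append(asvs[i_idx]); rec_j.append(j); rec_k.append(k)
                        rec_d.append(d_obs); rec_m.append(m); rec_s.append(s); rec_z.append(z)
                else:
                    for j in donors:
                        ranks = _sample_min_ranks(pmf, M, rng)
                        logn = logd[ranks]
                        m, s = float(logn.mean()), float(logn.std(ddof=1))
                        z = (log_dobs - m) / s if s > 0 else np.nan
                        rec_asv.append(asvs[i_idx]); rec_j.append(j); rec_k.append(k)
                        rec_d.append(d_obs); rec_m.append(m); rec_s.append(s); rec_z.append(z)
            else:  # pair pool: taxa of j union k, minus focal
                for j in donors:
                    j_idx = samples.index(j)
                    pool_mask = (P[:, j_idx] | P[:, k_idx])
                    pool_mask[i_idx] = False
                    pool_idx = np.where(pool_mask)[0]
                    if n_k > pool_idx.size:
                        raise ValueError(
                            f"pair pool smaller than N_k for {asvs[i_idx]} in ({j},{k})"
                        )
                    d_sorted = np.sort(sub[i_idx, pool_idx])
                    pmf = pmf_for(pool_idx.size, n_k)
                    logd = np.log(np.maximum(d_sorted, floor))
                    ranks = _sample_min_ranks(pmf, M, rng)
                    logn = logd[ranks]
                    m, s = float(logn.mean()), float(logn.std(ddof=1))
                    z = (log_dobs - m) / s if s > 0 else np.nan
                    rec_asv.append(asvs[i_idx]); rec_j.append(j); rec_k.append(k)
                    rec_d.append(d_obs); rec_m.append(m); rec_s.append(s); rec_z.append(z)

    if n_floored:
        logger.info("floored %d zero/near-zero observed distances at %g", n_floored, floor)
    table = pd.DataFrame(
        {
            "asv": rec_asv,
            "donor_sample": rec_j,
            "recipient_sample": rec_k,
            "d_obs": rec_d,
            "null_mean_log": rec_m,
            "null_sd_log": rec_s,
            "z": rec_z,
        }
    )
    n_deg = int(table["z"].isna().sum()) if len(table) else 0
    if n_deg:
        logger.info("%d records with degenerate null (sd=0) flagged NaN", n_deg)
    return table


def aggregate_phyloscores(
    table: pd.DataFrame, all_asvs: list[str] | None = None
) -> pd.DataFrame:
    """Per-ASV aggregates of the z records: total (sum), mean, median,
    n_pairs and mean/sd.

    The total is the default phylofactorization input; the alternatives are
    emitted so robustness to the aggregation choice can be re-checked
    cheaply. ASVs with no records (never uniquely present) get total = 0 and
    n_pairs = 0.
    """
    valid = table.dropna(subset=["z"]) if len(table) else table
    if len(valid):
        g = valid.groupby("asv")["z"]
        out = pd.DataFrame(
            {
                "total": g.sum(),
                "mean": g.mean(),
                "median": g.median(),
                "n_pairs": g.count(),
                "mean_over_sd": g.mean() / g.std(ddof=1),
            }
        )
    else:
        out = pd.DataFrame(columns=list(SUMMARY_METRICS))
    if all_asvs is not None:
        out = out.reindex(all_asvs)
        out["total"] = out["total"].fillna(0.0)
        out["n_pairs"] = out["n_pairs"].fillna(0).astype(int)
    else:
        out["n_pairs"] = out["n_pairs"].astype(int)
    out.index.name = "asv"
    return out
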