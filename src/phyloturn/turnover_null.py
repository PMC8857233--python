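"""Community-level turnover null models: betaMNTD, betaNTI, Bray-Curtis and
Raup-Crick (RC_Bray), plus assignment of the dominant assembly process per
sample pair.

Decision rules per pair (strict inequalities; boundary values fall through):

* betaNTI < -2            -> homogeneous selection
* betaNTI > +2            -> variable selection
* else RC_Bray < -0.95    -> homogenizing dispersal
* else RC_Bray > +0.95    -> dispersal limitation
* otherwise               -> undominated

The betaNTI null randomizes, per replicate, which tree tips carry each
sample's membership; the patristic distance pool is preserved. By default
each sample's membership is permuted independently, so even two samples with
identical membership face a non-degenerate null (their observed betaMNTD of
0 then scores far below it). ``shuffle="joint"`` applies one permutation to
both samples, the classic variant under which identical-membership pairs
have a degenerate (sd = 0) null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "bmntd",
    "bnti",
    "bray_curtis",
    "rc_bray",
    "classify_pair",
    "assign_processes",
    "process_fractions",
]

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
    "undefined",
)


@dataclass
class NullConfig:
    """Replication/seed settings for the turnover nulls."""

    n_reps: int = 999
    seed: int | None = None
    weighting: str = "abundance"  # or "presence"
    shuffle: str = "independent"  # or "joint"

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.weighting not in ("abundance", "presence"):
            raise ValueError("weighting must be 'abundance' or 'presence'")
        if self.shuffle not in ("independent", "joint"):
            raise ValueError("shuffle must be 'independent' or 'joint'")


def _prep(matrix: pd.DataFrame, dist, samples: tuple[str, str]):
    a, b = samples
    ids = list(dist.ids)
    pos = {t: i for i, t in enumerate(ids)}
    idx = np.array([pos[t] for t in matrix.index])
    D = np.asarray(dist.data)[np.ix_(idx, idx)]
    xa = matrix[a].to_numpy(float)
    xb = matrix[b].to_numpy(float)
    return D, xa, xb


def _bmntd_vectors(D: np.ndarray, xa: np.ndarray, xb: np.ndarray, weighting: str):
    pa, pb = xa > 0, xb > 0
    ua = pa & ~pb
    ub = pb & ~pa
    if not ua.any() and not ub.any():
        return 0.0, True
    dists, weights = [], []
    if ua.any():
        d = D[np.ix_(np.where(ua)[0], np.where(pb)[0])].min(axis=1)
        w = xa[ua] / xa[pa].sum() if weighting == "abundance" else np.ones(d.size)
        dists.append(d)
        weights.append(w)
    if ub.any():
        d = D[np.ix_(np.where(ub)[0], np.where(pa)[0])].min(axis=1)
        w = xb[ub] / xb[pb].sum() if weighting == "abundance" else np.ones(d.size)
        dists.append(d)
        weights.append(w)
    d = np.concatenate(dists)
    w = np.concatenate(weights)
    return float((d * w).sum() / w.sum()), False


def bmntd(sample_a: str, sample_b: str, matrix: pd.DataFrame, dist,
          weighting: str = "abundance") -> float:
    """Between-community mean nearest taxon distance.

    For each ASV present in exactly one of the two samples, take its minimum
    patristic distance to the taxa present in the other sample; return the
    weighted mean of those distances. Abundance weighting uses the focal
    ASV's relative abundance in its own sample, renormalized over the
    contributing ASVs; presence weighting is the simple mean. Identical
    membership gives 0.
    """
    D, xa, xb = _prep(matrix, dist, (sample_a, sample_b))
    if not (xa > 0).any() or not (xb > 0).any():
        raise ValueError("both samples must be non-empty")
    value, identical = _bmntd_vectors(D, xa, xb, weighting)
    if identical:
        logger.info("samples %s and %s have identical membership; betaMNTD = 0",
                    sample_a, sample_b)
    return value


def bnti(sample_a: str, sample_b: str, matrix: pd.DataFrame, dist,
         config: NullConfig | None = None) -> float:
    """betaNTI: z-score of the observed betaMNTD against a tip-shuffling null.

    Returns NaN (flagged sentinel) when the null has zero spread.
    """
    config = config or NullConfig()
    if config.n_reps < 2:
        raise ValueError("betaNTI needs n_reps >= 2")
    if str(sample_b) < str(sample_a):  # canonical order: z(a,b) == z(b,a) bit-wise
        sample_a, sample_b = sample_b, sample_a
    D, xa, xb = _prep(matrix, dist, (sample_a, sample_b))
    obs, _ = _bmntd_vectors(D, xa, xb, config.weighting)
    rng = np.random.default_rng(config.seed)
    n = D.shape[0]
    null = np.empty(config.n_reps)
    for r in range(config.n_reps):
        pa = rng.permutation(n)
        pb = rng.permutation(n) if config.shuffle == "independent" else pa
        ya, yb = np.zeros(n), np.zeros(n)
        ya[pa] = xa
        yb[pb] = xb
        null[r], _ = _bmntd_vectors(D, ya, yb, config.weighting)
    sd = null.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate betaNTI null for (%s, %s)", sample_a, sample_b)
        return float("nan")
    return float((obs - null.mean()) / sd)


def bray_curtis(sample_a: str, sample_b: str, matrix: pd.DataFrame) -> float:
    """Bray-Curtis dissimilarity on relative abundances: 1 - 2 sum(min) / sum."""
    xa = matrix[sample_a].to_numpy(float)
    xb = matrix[sample_b].to_numpy(float)
    if xa.sum() == 0 or xb.sum() == 0:
        raise ValueError("Bray-Curtis undefined for an all-zero sample")
    xa = xa / xa.sum()
    xb = xb / xb.sum()
    return float(1.0 - 2.0 * np.minimum(xa, xb).sum() / (xa + xb).sum())


def _integer_totals(matrix: pd.DataFrame, depth: int = 2000) -> np.ndarray:
    """Per-sample integer totals for the RC null (observed counts if the table
    holds counts, otherwise a fixed depth)."""
    vals = matrix.to_numpy(float)
    if np.allclose(vals, np.round(vals)) and vals.max() > 1:
        return np.round(vals.sum(axis=0)).astype(int)
    return np.full(matrix.shape[1], depth)


def _rc_null_sample(rng, richness, total, occ_p, abund_p):
    """One null community: richness taxa by occupancy, abundance fill by
    regional relative abundance (1 seed individual per chosen taxon, remainder
    with replacement)."""
    n = occ_p.size
    chosen = rng.choice(n, size=richness, replace=False, p=occ_p)
    counts = np.zeros(n)
    counts[chosen] = 1.0
    extra = total - richness
    if extra > 0:
        p = abund_p[chosen]
        p = p / p.sum()
        counts[chosen] += rng.multinomial(extra, p)
    return counts


def rc_bray(sample_a: str, sample_b: str, matrix: pd.DataFrame,
            config: NullConfig | None = None,
            pool_samples: list[str] | None = None) -> float:
    """Raup-Crick index on Bray-Curtis, in [-1, 1].

    Null communities preserve each sample's richness and total abundance:
    membership drawn with probability proportional to regional occupancy,
    abundance filled proportionally to regional relative abundance. RC is
    the doubled, centered empirical CDF position of the observed BC among
    the null BCs, ties at half weight.
    """
    config = config or NullConfig()
    rng = np.random.default_rng(config.seed)
    pool = matrix if pool_samples is None else matrix[pool_samples]
    occ = (pool > 0).sum(axis=1).to_numpy(float)
    keep = occ > 0
    if keep.sum() < 2:
        logger.warning("degenerate regional pool (<2 ASVs); RC undefined")
        return float("nan")
    occ_p = occ[keep] / occ[keep].sum()
    tot = pool.sum(axis=1).to_numpy(float)[keep]
    abund_p = tot / tot.sum()

    sub = matrix.loc[matrix.index[keep]]
    obs = bray_curtis(sample_a, sample_b, sub)
    totals = dict(zip(matrix.columns, _integer_totals(matrix)))
    rich_a = int((sub[sample_a] > 0).sum())
    rich_b = int((sub[sample_b] > 0).sum())

    less = ties = 0
    for _ in range(config.n_reps):
        na = _rc_null_sample(rng, rich_a, max(totals[sample_a], rich_a), occ_p, abund_p)
        nb = _rc_null_sample(rng, rich_b, max(totals[sample_b], rich_b), occ_p, abund_p)
        bc = 1.0 - 2.0 * np.minimum(na / na.sum(), nb / nb.sum()).sum() / 2.0
        if np.isclose(bc, obs):
            ties += 1
        elif bc < obs:
            less += 1
    return float(2.0 * (less + 0.5 * ties) / config.n_reps - 1.0)


def classify_pair(bnti_val: float, rc_val: float | None) -> str:
    """Assembly process from the strict threshold rules (boundaries fall through)."""
    if np.isnan(bnti_val):
        return "undefined"
    if bnti_val < -2:
        return "homogeneous_selection"
    if bnti_val > 2:
        return "variable_selection"
    if rc_val is None or np.isnan(rc_val):
        return "undefined"
    if rc_val < -0.95:
        return "homogenizing_dispersal"
    if rc_val > 0.95:
        return "dispersal_limitation"
    return "undominated"


def assign_processes(matrix: pd.DataFrame, dist,
                     config: NullConfig | None = None,
                     groups: pd.Series | dict | None = None) -> pd.DataFrame:
    """Per-sample-pair turnover statistics and dominant assembly process.

    RC_Bray is only computed for pairs with |betaNTI| <= 2 (selection takes
    precedence). Returns one row per unordered pair with columns sample_a,
    sample_b, bmntd, bnti, bray_curtis, rc_bray, process and, when groups
    are given, stratum ('within'/'between').
    """
    config = config or NullConfig()
    samples = list(matrix.columns)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    master = np.random.default_rng(config.seed)
    if groups is not None:
        groups = pd.Series(groups)
    rows = []
    for a, b in itertools.combinations(samples, 2):
        sub_seed = int(master.integers(2**31 - 1))
        cfg = NullConfig(config.n_reps, sub_seed, config.weighting, config.shuffle)
        bm = bmntd(a, b, matrix, dist, config.weighting)
        zn = bnti(a, b, matrix, dist, cfg)
        bc = bray_curtis(a, b, matrix)
        rc = np.nan
        if not np.isnan(zn) and -2 <= zn <= 2:
            rc = rc_bray(a, b, matrix, cfg)
        row = {
            "sample_a": a, "sample_b": b, "bmntd": bm, "bnti": zn,
            "bray_curtis": bc, "rc_bray": rc,
            "process": classify_pair(zn, rc),
        }
        if groups is not None:
            row["stratum"] = "within" if groups.get(a) == groups.get(b) else "between"
        rows.append(row)
    return pd.DataFrame(rows)


def process_fractions(pairs: pd.DataFrame, by_stratum: bool = False) -> pd.DataFrame:
    """Fraction of sample pairs assigned to each process (sums to 1)."""
    def frac(df):
        return df["process"].value_counts(normalize=True).reindex(PROCESSES, fill_value=0.0)

    if by_stratum and "stratum" in pairs:
        return pairs.groupby("stratum").apply(frac, include_groups=False)
    return frac(pairs).to_frame("fraction").T
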