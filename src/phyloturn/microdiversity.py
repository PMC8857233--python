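"""Screens for putative microdiversity within clades.

Two complementary signals are examined per clade against the background
(non-clade) tips:

* fine-scale diversification — the distribution of nearest taxon distances
  (NTD, each tip's shortest patristic distance to any other tip) shifted
  towards lower values;
* fine-scale ecological differentiation — the nucleotide similarity between
  each ASV and its beta-nearest ASVs (the phylogenetically closest ASV in
  each community lacking the focal one) shifted towards higher values, with
  the fraction of replacements at > 97% identity as the putative-ecotype
  criterion.

A per-clade rarefaction (hypergeometric subsampling of the clade's total
counts) checks that clades are sampled to saturation, the guard against
artificially sparse presence/absence patterns in undersampled clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "CladeReport",
    "ntd",
    "pairwise_identity",
    "beta_nearest_similarity",
    "clade_microdiversity_report",
    "clade_rarefaction",
    "depth_vs_ntd",
]


@dataclass
class AlignmentParams:
    """Needleman-Wunsch scoring for the internal pairwise aligner.

    Identity is counted over alignment columns excluding terminal gaps
    (end-gap-free semantics suit amplicons of unequal trimming).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def __post_init__(self):
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")

    def aligner(self):
        from Bio import Align

        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def ntd(tree_or_dist) -> pd.Series:
    """Nearest taxon distance per tip: min patristic distance to any other tip."""
    dist = tree_or_dist
    if hasattr(tree_or_dist, "tip_tip_distances"):
        dist = tree_or_dist.tip_tip_distances()
    D = np.asarray(dist.data, float).copy()
    if D.shape[0] < 2:
        raise ValueError("need >= 2 tips")
    np.fill_diagonal(D, np.inf)
    return pd.Series(D.min(axis=1), index=list(dist.ids), name="ntd")


def _trim_terminal_gaps(a: str, b: str) -> tuple[str, str]:
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    return a[start:end], b[start:end]


def pairwise_identity(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Percent identity of a global alignment, denominator = alignment columns
    excluding terminal gaps."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    aln = params.aligner().align(seq_a, seq_b)[0]
    ga, gb = _trim_terminal_gaps(str(aln[0]), str(aln[1]))
    if not ga:
        return 0.0
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return 100.0 * matches / len(ga)


def beta_nearest_similarity(
    matrix: pd.DataFrame,
    dist,
    seqs: dict[str, str],
    params: AlignmentParams | None = None,
    identity_matrix: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Nucleotide identity between each ASV and its beta-nearest ASVs.

    For each focal ASV and each sample where it is absent (but present
    somewhere), the beta-nearest ASV is the phylogenetically closest taxon
    present there; ties on distance average their identities. Presence/absence
    only — abundances never enter.

    Returns (per-ASV median identity, long table with one row per
    focal-ASV x absent-sample replacement). ASVs present in every sample are
    excluded with a log entry.
    """
    params = params or AlignmentParams()
    missing = [a for a in matrix.index if a not in seqs and identity_matrix is None]
    if missing:
        raise ValueError(f"ASVs without sequences: {missing[:10]}")
    ids = list(dist.ids)
    pos = {t: i for i, t in enumerate(ids)}
    idx = np.array([pos[a] for a in matrix.index])
    D = np.asarray(dist.data)[np.ix_(idx, idx)]
    P = matrix.values > 0
    asvs = list(matrix.index)
    samples = list(matrix.columns)

    cache: dict[tuple[str, str], float] = {}

    def ident(a: str, b: str) -> float:
        if identity_matrix is not None:
            return float(identity_matrix.loc[a, b])
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = pairwise_identity(seqs[a], seqs[b], params)
        return cache[key]

    rows = []
    for i, a in enumerate(asvs):
        if not P[i].any():
            continue
        absent = np.where(~P[i])[0]
        if absent.size == 0:
            logger.info("ASV %s present in every sample; no beta-nearest value", a)
            continue
        for k in absent:
            present = np.where(P[:, k])[0]
            present = present[present != i]
            if present.size == 0:
                continue
            d = D[i, present]
            dmin = d.min()
            nearest = present[np.isclose(d, dmin)]
            sim = float(np.mean([ident(a, asvs[j]) for j in nearest]))
            rows.append((a, samples[k], dmin, sim))
    long = pd.DataFrame(rows, columns=["asv", "sample", "distance", "identity"])
    medians = long.groupby("asv")["identity"].median() if len(long) else pd.Series(dtype=float)
    medians.name = "median_identity"
    return medians, long


@dataclass
class CladeReport:
    """Microdiversity screen of one clade against the background tips."""

    clade_id: str
    n_tips: int
    ntd_values: pd.Series = field(repr=False, default=None)
    background_ntd: pd.Series = field(repr=False, default=None)
    beta_similarity: pd.Series = field(repr=False, default=None)
    background_similarity: pd.Series = field(repr=False, default=None)
    frac_over_97: float = float("nan")
    background_frac_over_97: float = float("nan")
    p_ntd: float = float("nan")
    p_similarity: float = float("nan")
    underpowered: bool = False


def clade_microdiversity_report(
    clade_tips,
    background_tips,
    tree,
    matrix: pd.DataFrame,
    seqs: dict[str, str] | None = None,
    dist=None,
    params: AlignmentParams | None = None,
    clade_id: str = "clade",
    similarity: tuple[pd.Series, pd.DataFrame] | None = None,
) -> CladeReport:
    """NTD and beta-nearest-similarity distributions, clade vs background,
    with two-sided Wilcoxon rank-sum p-values and the >97% replacement
    fractions (computed on per-replacement values).

    ``similarity`` can pass a precomputed ``beta_nearest_similarity`` result
    to avoid re-aligning when several clades are screened.
    """
    clade = sorted(set(clade_tips))
    background = sorted(set(background_tips))
    if not clade:
        raise ValueError("empty clade")
    if dist is None:
        dist = tree.tip_tip_distances()
    ntd_all = ntd(dist)
    rep = CladeReport(clade_id=clade_id, n_tips=len(clade))
    rep.ntd_values = ntd_all.reindex(clade).dropna()
    rep.background_ntd = ntd_all.reindex(background).dropna()
    if len(clade) < 2 or len(background) < 2:
        rep.underpowered = True

    if seqs is not None or similarity is not None:
        if similarity is None:
            similarity = beta_nearest_similarity(matrix, dist, seqs, params)
        medians, long = similarity
        rep.beta_similarity = medians.reindex(clade).dropna()
        rep.background_similarity = medians.reindex(background).dropna()
        in_clade = long["asv"].isin(set(clade))
        in_bg = long["asv"].isin(set(background))
        if in_clade.any():
            rep.frac_over_97 = float((long.loc[in_clade, "identity"] > 97.0).mean())
        if in_bg.any():
            rep.background_frac_over_97 = float((long.loc[in_bg, "identity"] > 97.0).mean())
        if len(rep.beta_similarity) >= 2 and len(rep.background_similarity) >= 2:
            rep.p_similarity = float(
                stats.ranksums(rep.beta_similarity, rep.background_similarity).pvalue
            )
    if len(rep.ntd_values) >= 2 and len(rep.background_ntd) >= 2:
        rep.p_ntd = float(stats.ranksums(rep.ntd_values, rep.background_ntd).pvalue)
    return rep


def clade_rarefaction(
    matrix: pd.DataFrame,
    clade_tips,
    depths,
    reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Rarefaction curve of a clade's ASV richness.

    Subsamples ``depth`` of the clade's pooled counts without replacement
    (multivariate hypergeometric) and reports mean +/- sd richness per depth.
    Depths beyond the total are truncated with a warning.
    """
    rng = np.random.default_rng(rng)
    clade = [t for t in clade_tips if t in matrix.index]
    counts = np.round(matrix.loc[clade].sum(axis=1).to_numpy(float)).astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("clade has no counts in the table")
    rows = []
    for depth in depths:
        d = int(depth)
        if d > total:
            logger.warning("depth %d exceeds total %d; truncated", d, total)
            d = total
        rich = np.empty(reps)
        for r in range(reps):
            draw = rng.multivariate_hypergeometric(counts, d)
            rich[r] = np.count_nonzero(draw)
        rows.append({"depth": d, "mean_richness": rich.mean(),
                     "sd_richness": rich.std(ddof=1) if reps > 1 else 0.0})
    return pd.DataFrame(rows)


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form expected richness under hypergeometric subsampling:
    sum_i 1 - C(N - n_i, d) / C(N, d)."""
    counts = np.asarray(counts, float)
    N = counts.sum()
    from scipy.special import gammaln

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for n_i in counts:
        if N - n_i < depth:
            out += 1.0
        else:
            out += 1.0 - np.exp(logC(N - n_i, depth) - logC(N, depth))
    return float(out)


def depth_vs_ntd(tree) -> tuple[float, float]:
    """Spearman correlation between each tip's root distance (phylogenetic
    depth) and its NTD. Returns (nan, nan) when either has zero variance."""
    depths, names = [], []
    for tip in tree.tips():
        depths.append(tip.accumulate_to_ancestor(tree))
        names.append(tip.name)
    nt = ntd(tree).reindex(names).to_numpy()
    depths = np.asarray(depths)
    if np.allclose(nt, nt[0]) or np.allclose(depths, depths[0]):
        logger.info("zero variance in depth or NTD; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(depths, nt)
    return float(rho), float(p)
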