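"""Phylofactorization of per-ASV scores.

Sequentially cuts the tree edge that best separates the per-tip scores on its
two sides, where "best" is the absolute value of the equal-variance
two-sample t statistic. Each cut splits one connected component (bin) of the
tree into two, so after f factors the tips are partitioned into f + 1 bins
and every reported clade is monophyletic within its bin. Clades whose mean
score is below their complement's are labelled HoS (homogeneous selection,
low phylogenetic turnover); above, HeS.

Deterministic given the scores: no RNG; objective ties break on the smallest
edge index (preorder order of the edge's child node).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "Factor",
    "edge_objective",
    "phylofactorize",
    "consensus_taxonomy",
    "classify_clades",
]


@dataclass
class Factor:
    """One phylofactorization cut."""

    index: int
    edge: int
    clade_tips: set[str]
    complement_tips: set[str]
    t_stat: float
    p_value: float
    p_adjusted: float
    direction: str  # "HoS" or "HeS"
    consensus_taxonomy: str = ""

    @property
    def size(self) -> int:
        return len(self.clade_tips)


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t statistic and two-sided p."""
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def edge_objective(clade_scores, complement_scores) -> tuple[float, float]:
    """|t| objective for one candidate edge: pooled-variance two-sample t on
    the scores of the tips on either side. Requires >= 2 scored tips per side."""
    x = np.asarray(clade_scores, float)
    y = np.asarray(complement_scores, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each side needs >= 2 scored tips")
    return pooled_t(x, y)


def _edge_table(tree: TreeNode, tip_index: dict[str, int]):
    """Preorder list of non-root edges with boolean below-tip masks."""
    n_tips = len(tip_index)
    below = []
    for node in tree.preorder(include_self=False):
        mask = np.zeros(n_tips, dtype=bool)
        for t in ([node] if node.is_tip() else node.tips()):
            if t.name in tip_index:
                mask[tip_index[t.name]] = True
        below.append(mask)
    return np.array(below)


def phylofactorize(
    tree: TreeNode,
    summaries: pd.DataFrame | pd.Series,
    metric: str = "total",
    max_factors: int = 20,
    alpha: float = 0.05,
    taxonomy: pd.DataFrame | None = None,
    min_side: int = 2,
) -> list[Factor]:
    """Iteratively cut the globally best edge among all bins.

    Parameters
    ----------
    summaries : per-ASV score table (from ``aggregate_phyloscores``) or a
        Series of scores indexed by tip name.
    metric : column of ``summaries`` to use (default "total").
    max_factors : hard cap on the number of cuts.
    alpha : stop when the best edge's Bonferroni-adjusted p (corrected by the
        number of admissible edges tested that iteration) exceeds this.

    Tips without a finite score are dropped with a warning.
    """
    scores = summaries[metric] if isinstance(summaries, pd.DataFrame) else summaries
    scores = scores.astype(float)
    tip_names = [t.name for t in tree.tips()]
    scored = [t for t in tip_names if t in scores.index and np.isfinite(scores[t])]
    dropped = len(tip_names) - len(scored)
    if dropped:
        logger.warning("%d tips without a finite %s score dropped", dropped, metric)
    if len(scored) < 4:
        logger.warning("fewer than 4 scored tips; nothing to factor")
        return []
    tip_index = {t: i for i, t in enumerate(scored)}
    s = scores[scored].to_numpy()
    s2 = s * s

    below = _edge_table(tree, tip_index)  # (n_edges, n_tips)
    n_edges = below.shape[0]
    edge_bin = np.zeros(n_edges, dtype=int)  # component of each edge
    tip_bin = np.zeros(len(scored), dtype=int)
    n_bins = 1

    factors: list[Factor] = []
    for f in range(1, max_factors + 1):
        best = None  # (|t|, edge_idx, t, p, n_tested)
        n_tested = 0
        for b in range(n_bins):
            bin_tips = tip_bin == b
            nb = int(bin_tips.sum())
            if nb < 2 * min_side:
                continue
            edges = np.where(edge_bin == b)[0]
            if edges.size == 0:
                continue
            inb = below[edges] & bin_tips  # distal tips within the bin
            n1 = inb.sum(axis=1)
            ok = (n1 >= min_side) & (nb - n1 >= min_side)
            if not ok.any():
                continue
            e_ok = edges[ok]
            n1 = n1[ok].astype(float)
            n2 = nb - n1
            sum1 = inb[ok] @ s
            sumsq1 = inb[ok] @ s2
            sum_all = s[bin_tips].sum()
            sumsq_all = s2[bin_tips].sum()
            m1 = sum1 / n1
            m2 = (sum_all - sum1) / n2
            ss1 = sumsq1 - n1 * m1**2
            ss2 = (sumsq_all - sumsq1) - n2 * m2**2
            df = n1 + n2 - 2
            sp2 = (ss1 + ss2) / df
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            t = np.where(np.isfinite(t), t, 0.0)
            n_tested += int(e_ok.size)
            order = np.argsort(np.abs(t))[::-1]
            for o in order[:1]:
                # tie-break on smallest edge index among equal |t|
                tied = np.where(np.isclose(np.abs(t), np.abs(t[o])))[0]
                pick = tied[np.argmin(e_ok[tied])]
                cand = (float(abs(t[pick])), int(e_ok[pick]), float(t[pick]), float(df[pick]))
                if best is None or cand[0] > best[0] or (
                    np.isclose(cand[0], best[0]) and cand[1] < best[1]
                ):
                    best = cand
        if best is None or n_tested == 0:
            if f == 1:
                logger.warning("no admissible edge at the first iteration")
            break
        abs_t, e_idx, t_val, dof = best
        p = float(2.0 * stats.t.sf(abs_t, dof))
        p_adj = min(1.0, p * n_tested)
        if p_adj > alpha:
            break
        b = edge_bin[e_idx]
        clade_mask = below[e_idx] & (tip_bin == b)
        comp_mask = (tip_bin == b) & ~clade_mask
        clade = {t for t, i in tip_index.items() if clade_mask[i]}
        comp = {t for t, i in tip_index.items() if comp_mask[i]}
        direction = "HoS" if s[clade_mask].mean() < s[comp_mask].mean() else "HeS"
        factor = Factor(f, e_idx, clade, comp, t_val, p, p_adj, direction)
        if taxonomy is not None:
            factor.consensus_taxonomy = consensus_taxonomy(clade, taxonomy)
        factors.append(factor)
        # split bin b: the clade becomes a new bin
        new_bin = n_bins
        n_bins += 1
        tip_bin[clade_mask] = new_bin
        # edges whose below-tips are a subset of the cut edge's move to the new bin
        desc = ~(below & ~below[e_idx]).any(axis=1) & (edge_bin == b)
        desc[e_idx] = False
        edge_bin[desc] = new_bin
        edge_bin[e_idx] = -1  # consumed
    return factors


def bin_partition(tree: TreeNode, factors: list[Factor]) -> pd.Series:
    """Tip -> bin label after the given factors (bin 0 = residual backbone)."""
    tips = [t.name for t in tree.tips()]
    lab = pd.Series(0, index=tips, dtype=int)
    for fac in factors:
        lab[list(fac.clade_tips)] = fac.index
    return lab


def consensus_taxonomy(tips, taxonomy: pd.DataFrame, threshold: float = 0.95) -> str:
    """Deepest lineage shared by >= ``threshold`` of the classified tips.

    Ranks are scanned from domain down; at each rank only tips classified at
    that rank vote. Returns "Unclassified" when no tip has taxonomy.
    """
    present = [t for t in tips if t in taxonomy.index]
    if not present:
        return "Unclassified"
    sub = taxonomy.loc[present].fillna("")
    lineage = []
    for rank in sub.columns:
        vals = sub[rank][sub[rank].astype(str).str.len() > 0]
        if len(vals) == 0:
            break
        top = vals.value_counts()
        name, count = top.index[0], top.iloc[0]
        if count / len(vals) >= threshold:
            lineage.append(str(name))
        else:
            break
    return ";".join(lineage) if lineage else "Unclassified"


def classify_clades(factors: list[Factor], summaries: pd.DataFrame | None = None,
                    metric: str = "total") -> pd.DataFrame:
    """Per-clade report: direction, size, score stats and significance."""
    rows = []
    for fac in factors:
        row = {
            "factor": fac.index,
            "direction": fac.direction,
            "n_tips": fac.size,
            "t_stat": fac.t_stat,
            "p_value": fac.p_value,
            "p_adjusted": fac.p_adjusted,
            "consensus_taxonomy": fac.consensus_taxonomy,
        }
        if summaries is not None:
            vals = summaries.loc[list(fac.clade_tips), metric]
            row.update(score_mean=float(vals.mean()), score_median=float(vals.median()))
        rows.append(row)
    return pd.DataFrame(rows)
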