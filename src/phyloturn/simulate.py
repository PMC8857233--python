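"""Synthetic data with known ground truth.

Generates the substrate on which the whole stack is testable at desk scale:

* uniform-attachment random trees ("rtree"-like topology, iid exponential
  branch lengths, mean 0.05 substitutions/site),
* community matrices with a planted homogeneous-selection (HoS) clade —
  near-total clade-wise occupancy achieved through low per-ASV occupancy,
  i.e. members replace one another across samples — or a planted
  heterogeneous-selection (HeS) clade confined to one sample group,
* Jukes-Cantor sequences evolved along the tree (short within-clade branches
  give > 97% within-clade identity), and
* Brownian-motion niche traits with derived sample environment tables.

Every generator is bit-reproducible from its parameters and seed; the
returned :class:`SimTruth` records what was planted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "random_tree",
    "choose_clade",
    "shrink_clade_branches",
    "plant_hos_clade",
    "plant_hes_clade",
    "hos_dataset",
    "evolve_sequences",
    "bm_traits",
]

BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth recorded alongside a generated community matrix."""

    planted_clade_tips: list[str]
    planted_direction: str  # "HoS", "HeS" or "none"
    clade_occupancy: float
    per_asv_occupancy: float
    background_occupancy: float
    seed: int | None
    extras: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def random_tree(
    n_tips: int,
    rng: np.random.Generator | int | None = None,
    branch_mean: float = 0.05,
    model: str = "uniform",
    prefix: str = "ASV",
) -> TreeNode:
    """Random tree by sequential attachment of tips to uniformly chosen edges
    (``model="uniform"``) or to uniformly chosen *pendant* edges
    (``model="yule"``), with iid exponential branch lengths."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    if model not in ("uniform", "yule"):
        raise ValueError("model must be 'uniform' or 'yule'")
    rng = np.random.default_rng(rng)
    width = len(str(n_tips))
    names = [f"{prefix}_{i + 1:0{width}d}" for i in range(n_tips)]

    root = TreeNode()
    root.append(TreeNode(name=names[0]))
    root.append(TreeNode(name=names[1]))
    nodes = list(root.children)  # each non-root node stands for its parent edge
    for name in names[2:]:
        if model == "uniform":
            target = nodes[rng.integers(len(nodes))]
        else:
            tips = [nd for nd in nodes if nd.is_tip()]
            target = tips[rng.integers(len(tips))]
        parent = target.parent
        inner = TreeNode()
        parent.remove(target)
        parent.append(inner)
        inner.append(target)
        new_tip = TreeNode(name=name)
        inner.append(new_tip)
        nodes.extend([inner, new_tip])
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(branch_mean))
    root.length = 0.0
    return root


def choose_clade(tree: TreeNode, target_size: int) -> set[str]:
    """Tip set of the internal edge whose subtree size is closest to
    ``target_size`` (a convenient monophyletic clade to plant effects in)."""
    best, best_gap = None, None
    for node in tree.non_tips(include_self=False):
        tips = {t.name for t in node.tips()}
        gap = abs(len(tips) - target_size)
        if best_gap is None or gap < best_gap:
            best, best_gap = tips, gap
    if best is None:
        raise ValueError("tree has no internal edges")
    return best


def shrink_clade_branches(tree: TreeNode, clade_tips, factor: float = 0.1) -> TreeNode:
    """Copy of the tree with every branch inside the clade's subtree scaled by
    ``factor`` (used to plant short within-clade distances / microdiversity)."""
    tree = tree.copy()
    mrca = tree.lca([tree.find(t) for t in clade_tips])
    for node in mrca.traverse(include_self=False):
        node.length *= factor
    return tree


def _lognormal_abundances(rng, mask: np.ndarray, mu: float = 0.0, sigma: float = 1.0):
    out = np.zeros(mask.shape)
    out[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    return out


def plant_hos_clade(
    tree: TreeNode,
    clade,
    n_samples: int = 30,
    clade_occupancy: float = 1.0,
    per_asv_occupancy: float = 0.3,
    background_occupancy: float = 0.1,
    rng: np.random.Generator | int | None = None,
    seed_label: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Community matrix with a planted HoS clade.

    A ``clade_occupancy`` fraction of samples contains at least one clade
    member, while each member individually occurs in only a
    ``per_asv_occupancy`` fraction — the replacement structure that yields
    strongly negative phyloscores. Background tips occur iid at
    ``background_occupancy``; abundances are lognormal(0, 1) per occurrence
    (the phyloscore itself is abundance-blind).
    """
    rng = np.random.default_rng(rng)
    tips = [t.name for t in tree.tips()]
    clade = sorted(set(clade))
    unknown = set(clade) - set(tips)
    if unknown:
        raise ValueError(f"clade tips not in tree: {sorted(unknown)[:5]}")
    if clade and per_asv_occupancy > clade_occupancy:
        raise ValueError("per_asv_occupancy must be <= clade_occupancy")
    if clade and per_asv_occupancy * len(clade) < clade_occupancy:
        raise ValueError(
            "infeasible occupancies: need per_asv_occupancy * |clade| >= "
            f"clade_occupancy ({per_asv_occupancy} * {len(clade)} < {clade_occupancy})"
        )
    background = [t for t in tips if t not in set(clade)]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]

    pres = pd.DataFrame(False, index=tips, columns=samples)
    if clade:
        n_occ = int(round(clade_occupancy * n_samples))
        occupied = rng.choice(n_samples, size=n_occ, replace=False)
        p_in = min(1.0, per_asv_occupancy / clade_occupancy)
        for s in occupied:
            draw = rng.random(len(clade)) < p_in
            if not draw.any():
                draw[rng.integers(len(clade))] = True
            pres.loc[clade, samples[s]] = draw
    bg_draw = rng.random((len(background), n_samples)) < background_occupancy
    pres.loc[background, :] = bg_draw
    # no empty samples: force one background tip where needed
    for j, s in enumerate(samples):
        if not pres[s].any():
            pres.loc[background[rng.integers(len(background))], s] = True

    matrix = pd.DataFrame(
        _lognormal_abundances(rng, pres.values), index=tips, columns=samples
    )
    truth = SimTruth(
        planted_clade_tips=list(clade),
        planted_direction="HoS" if clade else "none",
        clade_occupancy=clade_occupancy,
        per_asv_occupancy=per_asv_occupancy,
        background_occupancy=background_occupancy,
        seed=seed_label,
    )
    return matrix, truth


def plant_hes_clade(
    tree: TreeNode,
    clade,
    sample_groups: dict[str, str],
    per_asv_occupancy: float = 0.6,
    background_occupancy: float = 0.1,
    rng: np.random.Generator | int | None = None,
    seed_label: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Community matrix with a planted HeS clade: clade members occur only in
    the first group's samples (confinement -> elevated phyloscores between
    groups). Background tips occur iid everywhere."""
    rng = np.random.default_rng(rng)
    tips = [t.name for t in tree.tips()]
    clade = sorted(set(clade))
    groups = pd.Series(sample_groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        logger.warning("single sample group: HeS planting degenerates to HoS-style occupancy")
    host = levels[0]
    samples = list(groups.index)
    background = [t for t in tips if t not in set(clade)]

    pres = pd.DataFrame(False, index=tips, columns=samples)
    host_samples = [s for s in samples if groups[s] == host]
    for s in host_samples:
        draw = rng.random(len(clade)) < per_asv_occupancy
        if len(clade) and not draw.any():
            draw[rng.integers(len(clade))] = True
        if clade:
            pres.loc[clade, s] = draw
    pres.loc[background, :] = rng.random((len(background), len(samples))) < background_occupancy
    for s in samples:
        if not pres[s].any():
            pres.loc[background[rng.integers(len(background))], s] = True
    matrix = pd.DataFrame(
        _lognormal_abundances(rng, pres.values), index=tips, columns=samples
    )
    truth = SimTruth(
        planted_clade_tips=list(clade),
        planted_direction="HeS" if clade else "none",
        clade_occupancy=float(len(host_samples)) / len(samples),
        per_asv_occupancy=per_asv_occupancy,
        background_occupancy=background_occupancy,
        seed=seed_label,
        extras={"host_group": host},
    )
    return matrix, truth


def hos_dataset(
    n_tips: int = 500,
    clade_size: int = 40,
    n_samples: int = 30,
    rng: np.random.Generator | int | None = None,
    clade_branch_factor: float = 0.05,
    clade_occupancy: float = 1.0,
    per_asv_occupancy: float = 0.3,
    background_occupancy: float = 0.1,
    seq_length: int | None = None,
    n_traits: int = 0,
    seed_label: int | None = None,
):
    """One self-consistent HoS study dataset: a random tree whose planted
    clade has short internal branches (scaled by ``clade_branch_factor``), a
    community matrix with near-total clade-wise but low per-ASV clade
    occupancy over a sparse background, and (optionally) JC sequences and
    Brownian niche traits.

    The defaults are the desk-scale study conditions used throughout the test
    suite. Returns a dict with keys tree, dist_source ("tree"), matrix,
    truth, clade, and optionally seqs, traits, env.
    """
    rng = np.random.default_rng(rng)
    tree = random_tree(n_tips, rng)
    clade = choose_clade(tree, clade_size)
    tree = shrink_clade_branches(tree, clade, clade_branch_factor)
    matrix, truth = plant_hos_clade(
        tree, clade, n_samples,
        clade_occupancy=clade_occupancy,
        per_asv_occupancy=per_asv_occupancy,
        background_occupancy=background_occupancy,
        rng=rng, seed_label=seed_label,
    )
    out = {"tree": tree, "matrix": matrix, "truth": truth, "clade": clade}
    if seq_length:
        out["seqs"] = evolve_sequences(tree, seq_length, rng=rng)
    if n_traits:
        traits, env = bm_traits(tree, n_traits=n_traits, rng=rng, matrix=matrix)
        out["traits"], out["env"] = traits, env
    return out


def evolve_sequences(
    tree: TreeNode,
    length: int = 300,
    rate_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Jukes-Cantor sequences along the tree.

    The root sequence is iid uniform over ACGT; along a branch of length d
    (x rate_scale, in expected substitutions/site) each site stays put with
    probability 1/4 + 3/4 exp(-4d/3), otherwise switches uniformly to one of
    the other three bases. Returns tip sequences only.
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = np.random.default_rng(rng)
    root_seq = rng.integers(4, size=length)
    seqs: dict[str, str] = {}

    def descend(node, seq):
        for child in node.children:
            d = (child.length or 0.0) * rate_scale
            p_same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
            child_seq = seq.copy()
            change = rng.random(length) >= p_same
            if change.any():
                shift = rng.integers(1, 4, size=int(change.sum()))
                child_seq[change] = (child_seq[change] + shift) % 4
            if child.is_tip():
                seqs[child.name] = "".join(BASES[child_seq])
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return seqs


def jc_expected_identity(d: float) -> float:
    """Closed-form expected percent identity between two sequences separated
    by total path length d (expected substitutions/site) under Jukes-Cantor."""
    return 100.0 * (0.25 + 0.75 * np.exp(-4.0 * d / 3.0))


def bm_traits(
    tree: TreeNode,
    sigma: float = 1.0,
    n_traits: int = 3,
    rng: np.random.Generator | int | None = None,
    matrix: pd.DataFrame | None = None,
    env_noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Brownian-motion niche traits per tip and, when a community matrix is
    given, a derived sample environment table.

    Along each branch of length t a trait drifts by Normal(0, sigma^2 t).
    The sample environment value is the abundance-weighted mean of the
    present tips' traits plus Normal(0, env_noise_sd * trait sd) measurement
    noise — data whose niche optima carry the tree's phylogenetic signal.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(rng)
    values: dict[str, np.ndarray] = {}

    def descend(node, val):
        for child in node.children:
            step = rng.normal(0.0, sigma * np.sqrt(child.length or 0.0), size=n_traits)
            v = val + step
            if child.is_tip():
                values[child.name] = v
            else:
                descend(child, v)

    descend(tree, np.zeros(n_traits))
    traits = pd.DataFrame.from_dict(values, orient="index",
                                    columns=[f"trait_{i + 1}" for i in range(n_traits)])
    env = None
    if matrix is not None:
        T = traits.loc[matrix.index].values
        A = matrix.values
        w = A / A.sum(axis=0, keepdims=True)
        env_vals = w.T @ T
        noise = rng.normal(0.0, env_noise_sd * T.std(axis=0), size=env_vals.shape)
        env = pd.DataFrame(env_vals + noise, index=matrix.columns, columns=traits.columns)
    return traits, env
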