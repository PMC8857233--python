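"""Input, validation and alignment of trees, abundance tables, sequences and taxonomy.

All downstream modules work on three congruent objects:

* a rooted :class:`skbio.TreeNode` with branch lengths in substitutions/site,
* a patristic :class:`skbio.DistanceMatrix` derived from it, and
* a community matrix as a :class:`pandas.DataFrame` (ASV rows x sample columns,
  non-negative abundances; presence = abundance > 0).

Branch lengths are mandatory: every distance in the framework is
substitution-scaled, so a tree without lengths is rejected rather than
defaulted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.io.format.newick import NewickFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "midpoint_root",
    "patristic_matrix",
    "read_abundance_table",
    "read_table",
    "read_fasta",
    "read_taxonomy",
    "filter_min_samples",
    "to_absolute",
    "validate_dataset",
    "ValidationReport",
]

#: canonical rank order for taxonomy lineages
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")


def _check_tree(tree: TreeNode) -> TreeNode:
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have >= 2 tips")
    names = [t.name for t in tips]
    if any(n is None for n in names):
        raise ValueError("every tip must be named")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate tip identifiers: {sorted(dupes)}")
    n_zero = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                "tree has edges without branch lengths; substitution-scaled "
                "distances are required (refusing to default lengths to 1)"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise ValueError(f"non-finite or negative branch length on {node.name!r}")
        if node.length == 0:
            n_zero += 1
    if tree.length is None:
        tree.length = 0.0
    if n_zero:
        logger.warning("tree contains %d zero-length edges", n_zero)
    return tree


def read_newick(path) -> TreeNode:
    """Read a rooted tree from a Newick file and validate it.

    Requires >= 2 uniquely named tips and a finite non-negative length on
    every edge. Zero-length edges are kept but logged.
    """
    text = Path(path).read_text()
    if not text.strip().endswith(";"):
        raise ValueError(f"Newick parse error in {path}: missing terminating ';'")
    try:
        tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    except NewickFormatError as exc:
        raise ValueError(f"Newick parse error in {path}: {exc}") from exc
    return _check_tree(tree)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Reroot at the midpoint of the longest tip-to-tip path.

    Patristic distances are invariant under this (or any) rerooting.
    """
    rooted = tree.root_at_midpoint()
    if rooted.length is None:
        rooted.length = 0.0
    return rooted


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """All pairwise tip-to-tip path-length (patristic) distances."""
    return tree.tip_tip_distances()


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_abundance_table(path, tree: TreeNode | None = None) -> pd.DataFrame:
    """Read an ASV x sample abundance TSV (header row, first column = ASV id).

    If a tree is given and the column labels — but not the row labels —
    unambiguously match tree tips, the table is assumed transposed and is
    flipped, with a log message.
    """
    df = _read_tsv(path).astype(float)
    if (df.values < 0).any():
        raise ValueError("abundance table contains negative entries")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        rows_match = len(tips & set(df.index)) > 0
        cols_match = len(tips & set(df.columns)) > 0
        if cols_match and not rows_match:
            logger.info("abundance table appears transposed (samples as rows); flipping")
            df = df.T
    if df.index.has_duplicates:
        raise ValueError("duplicate ASV ids in abundance table")
    return df


# backwards-friendly alias used by the CLI
read_table = read_abundance_table


def read_fasta(path) -> dict[str, str]:
    """Read sequences into an id -> string mapping (upper-cased)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        s = str(rec.seq).upper()
        if not s:
            raise ValueError(f"empty sequence for {rec.id!r}")
        seqs[rec.id] = s
    return seqs


def parse_lineage(lineage: str) -> list[str]:
    """Split a ';'-delimited lineage, stripping 'k__'-style prefixes.

    Missing ranks come back as empty strings (kept, never dropped) and the
    list is padded/truncated to the canonical six ranks (domain..genus).
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    out = []
    for p in parts:
        for pref in _PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        out.append(p)
    out = out[: len(RANKS)]
    out += [""] * (len(RANKS) - len(out))
    return out


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column (asv, lineage) or pre-split taxonomy TSV.

    Returns a DataFrame indexed by ASV id with the six canonical rank
    columns; unknown ranks are empty strings.
    """
    df = _read_tsv(path)
    if df.index.has_duplicates:
        raise ValueError("duplicate ASV ids in taxonomy table")
    if df.shape[1] == 1:
        rows = [parse_lineage(v) for v in df.iloc[:, 0]]
        return pd.DataFrame(rows, index=df.index, columns=list(RANKS))
    out = df.fillna("").astype(str)
    out.columns = [c.lower() for c in out.columns]
    return out


def filter_min_samples(matrix: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Drop ASVs present (abundance > 0) in fewer than ``min_samples`` samples.

    The default of 2 removes singleton occurrences, the usual guard against
    sequencing-error false positives. Idempotent; samples are never dropped.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    occ = (matrix > 0).sum(axis=1)
    kept = matrix.loc[occ >= min_samples]
    if kept.shape[0] == 0:
        raise ValueError("filter removed every ASV (empty dataset)")
    return kept


def to_absolute(matrix: pd.DataFrame, cell_counts: pd.Series | dict) -> pd.DataFrame:
    """Convert (relative or count) abundances to cells per gram.

    Each sample column is first closed to relative abundance, then multiplied
    by that sample's total cell count, so column sums equal the cell counts.
    """
    counts = pd.Series(cell_counts, dtype=float)
    missing = [s for s in matrix.columns if s not in counts.index]
    if missing:
        raise ValueError(f"missing cell counts for samples: {missing}")
    bad = [s for s in matrix.columns if not counts[s] > 0]
    if bad:
        raise ValueError(f"non-positive cell counts for samples: {bad}")
    colsum = matrix.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("cannot close an all-zero sample to relative abundance")
    rel = matrix.div(colsum, axis=1)
    return rel.mul(counts[matrix.columns], axis=1)


@dataclass
class ValidationReport:
    """Outcome of cross-checking tree/table/sequence/taxonomy congruence."""

    tips_not_in_table: list[str] = field(default_factory=list)
    table_not_in_tree: list[str] = field(default_factory=list)
    asvs_without_sequence: list[str] = field(default_factory=list)
    asvs_without_taxonomy: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)
    zero_length_edges: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.tips_not_in_table
            or self.table_not_in_tree
            or self.asvs_without_sequence
            or self.empty_samples
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok and not self.messages:
            return "dataset congruent"
        lines = []
        for k in (
            "tips_not_in_table",
            "table_not_in_tree",
            "asvs_without_sequence",
            "asvs_without_taxonomy",
            "empty_samples",
        ):
            v = getattr(self, k)
            if v:
                lines.append(f"{k}: {v[:10]}{'...' if len(v) > 10 else ''}")
        if self.zero_length_edges:
            lines.append(f"zero_length_edges: {self.zero_length_edges}")
        lines.extend(self.messages)
        return "\n".join(lines) or "dataset congruent"


def validate_dataset(
    tree: TreeNode,
    matrix: pd.DataFrame,
    seqs: dict[str, str] | None = None,
    taxonomy: pd.DataFrame | None = None,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check that tree tips, table rows and optional sequence/taxonomy
    ids all refer to the same ASV set.

    ``strict=True`` raises on any mismatch that would corrupt downstream
    distances (unmatched ids, empty samples).
    """
    tips = {t.name for t in tree.tips()}
    asvs = set(matrix.index)
    rep = ValidationReport()
    rep.tips_not_in_table = sorted(tips - asvs)
    rep.table_not_in_tree = sorted(asvs - tips)
    if seqs is not None:
        rep.asvs_without_sequence = sorted(asvs - set(seqs))
    if taxonomy is not None:
        rep.asvs_without_taxonomy = sorted(asvs - set(taxonomy.index))
    rep.empty_samples = [s for s in matrix.columns if not (matrix[s] > 0).any()]
    rep.zero_length_edges = sum(
        1 for n in tree.traverse(include_self=False) if n.length == 0
    )
    if strict and not rep.ok:
        raise ValueError(f"dataset incongruent:\n{rep}")
    return rep


def prune_to_shared(tree: TreeNode, matrix: pd.DataFrame):
    """Restrict tree and table to their shared ASV set (convenience)."""
    tips = {t.name for t in tree.tips()}
    shared = [a for a in matrix.index if a in tips]
    if len(shared) < 2:
        raise ValueError("fewer than 2 ASVs shared between tree and table")
    pruned = tree.shear(shared)
    pruned.prune()
    return pruned, matrix.loc[shared]
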