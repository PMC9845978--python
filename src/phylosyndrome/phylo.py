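"""Phylogeny input and patristic-distance structure.

Trees come in as Newick with branch lengths (dendropy does the parsing);
what the regression needs is the tip-tip patristic distance matrix on a
height-normalized tree, plus tip alignment against the trait matrix.
Distances are computed by a single postorder sweep (tip depths + lowest
common ancestor), which is orders of magnitude faster than per-pair path
queries and is checked against a graph shortest-path oracle in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .traits import TraitMatrix

#: relative jitter applied to coincident tips so the correlation matrix
#: stays non-singular (zero-length terminal branches are common in
#: GenBank-derived trees)
DEFAULT_JITTER = 1e-8


class TreeError(ValueError):
    """The input tree violates the contract (labels, lengths, size)."""


def read_newick(
    path: str | Path,
    missing_branch_length: float | None = None,
    schema: str = "newick",
) -> dendropy.Tree:
    """Read a rooted tree with branch lengths from Newick (or Nexus).

    Branch lengths are mandatory: an edge without a length raises unless
    ``missing_branch_length`` supplies a constant substitute (the
    correlation model is meaningless without lengths).  Duplicate or
    missing tip labels and trees with fewer than two tips are errors.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeError(f"could not parse {path} as {schema}: {exc}") from exc
    return validate_tree(tree, missing_branch_length=missing_branch_length)


def tree_from_string(newick: str, **kwargs) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return validate_tree(tree, **kwargs)


def validate_tree(
    tree: dendropy.Tree, missing_branch_length: float | None = None
) -> dendropy.Tree:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise TreeError(f"tree must have >= 2 tips, found {len(leaves)}")
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(lb is None for lb in labels):
        raise TreeError("every tip must carry a label")
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise TreeError(f"duplicate tip label(s): {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if missing_branch_length is None:
                raise TreeError(
                    "tree has edges without branch lengths; pass "
                    "missing_branch_length to substitute a constant"
                )
            edge.length = missing_branch_length
        elif edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    return tree


@dataclass
class PatristicDistances:
    """Symmetric tip-tip path-length matrix with its tip labels.

    ``height`` is the maximum root-to-tip depth of the tree the matrix was
    computed from (1.0 after normalization).
    """

    labels: list[str]
    matrix: np.ndarray
    height: float

    def __post_init__(self) -> None:
        D = np.asarray(self.matrix, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = D

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> "PatristicDistances":
        idx = [self.labels.index(lb) for lb in labels]
        return PatristicDistances(
            labels=list(labels),
            matrix=self.matrix[np.ix_(idx, idx)],
            height=self.height,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _tip_depths(tree: dendropy.Tree) -> tuple[list[str], np.ndarray, dict]:
    depths: dict = {tree.seed_node: 0.0}
    labels: list[str] = []
    tip_index: dict = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            tip_index[node] = len(labels)
            labels.append(node.taxon.label)
    depth_arr = np.array([depths[n] for n in tip_index], dtype=float)
    return labels, depth_arr, tip_index


def patristic_matrix(
    tree: dendropy.Tree,
    normalize: bool = True,
    jitter: float | None = DEFAULT_JITTER,
) -> PatristicDistances:
    """Tip-tip patristic distances: D_ij = branch-length sum on path i->j.

    Computed as depth_i + depth_j - 2*depth(LCA(i, j)) in one postorder
    sweep.  With ``normalize`` (the default) branch lengths are first
    scaled so the tree height is 1, putting the signal parameter of the
    regression in comparable units across trees.  Coincident tips
    (distance 0 between distinct tips) receive ``2 * jitter * height`` so
    downstream correlation matrices stay non-singular.
    """
    labels, depth, tip_index = _tip_depths(tree)
    n = len(labels)
    height = float(depth.max())
    if height <= 0:
        raise TreeError("tree height must be positive")
    depths_nodes: dict = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            depths_nodes[node] = 0.0
        else:
            depths_nodes[node] = depths_nodes[node.parent_node] + (node.edge.length or 0.0)

    if not _is_ultrametric(depth, height):
        warnings.warn(
            "tree is not ultrametric; height taken as max root-to-tip depth",
            stacklevel=2,
        )

    D = np.zeros((n, n), dtype=float)
    # postorder: each node carries the tip indices below it; tips in
    # different child subtrees have this node as their LCA
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = np.array([tip_index[node]], dtype=np.intp)
            continue
        groups = [below.pop(c) for c in node.child_nodes()]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                I, J = groups[a], groups[b]
                d = depth[I][:, None] + depth[J][None, :] - 2.0 * depths_nodes[node]
                D[np.ix_(I, J)] = d
                D[np.ix_(J, I)] = d.T
        below[node] = np.concatenate(groups)

    if normalize:
        D /= height
        out_height = 1.0
    else:
        out_height = height
    if jitter is not None:
        off = ~np.eye(n, dtype=bool)
        zero = off & (D <= 0)
        if zero.any():
            D[zero] = 2.0 * jitter * out_height
    return PatristicDistances(labels=labels, matrix=D, height=out_height)


def _is_ultrametric(tip_depths: np.ndarray, height: float, rtol: float = 1e-6) -> bool:
    return bool(np.allclose(tip_depths, height, rtol=rtol, atol=rtol * height))


@dataclass
class MatchReport:
    dropped_tips: list[str]
    dropped_species: list[str]


def match_tips(
    tree: dendropy.Tree, matrix: TraitMatrix
) -> tuple[dendropy.Tree, TraitMatrix, MatchReport]:
    """Prune tree and trait matrix to their common species, tip-ordered.

    Returns the pruned tree, the matrix with rows reordered to the pruned
    tree's tip order, and a report of what was dropped on each side.
    """
    tip_labels = [lf.taxon.label for lf in tree.leaf_nodes()]
    species = set(matrix.species_ids)
    common = [lb for lb in tip_labels if lb in species]
    if not common:
        raise TreeError("tree tips and trait-matrix species do not overlap")
    dropped_tips = [lb for lb in tip_labels if lb not in species]
    dropped_species = [sp for sp in matrix.species_ids if sp not in set(tip_labels)]
    if dropped_tips:
        tree = tree.extract_tree_with_taxa_labels(common)
        validate_tree(tree)
    ordered = [lf.taxon.label for lf in tree.leaf_nodes()]
    aligned = matrix.reordered(ordered)
    return tree, aligned, MatchReport(dropped_tips, dropped_species)
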