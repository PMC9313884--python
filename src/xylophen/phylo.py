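"""Phylogeny utilities: Newick I/O, variance–covariance matrices, Pagel's
lambda branch-length transform, tree pruning, and phylogenetically
independent contrasts.

Trees are :class:`dendropy.Tree` objects throughout; tip labels are the
species identifiers used in trait tables.  The phylogenetic
variance–covariance (VCV) matrix ``V`` has ``V[i, j]`` equal to the shared
root-to-MRCA branch length of tips *i* and *j*, so its diagonal holds
root-to-tip distances.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "read_tree",
    "write_tree",
    "vcv_matrix",
    "pagel_transform",
    "prune_tree",
    "independent_contrasts",
]


class TreeError(ValueError):
    """Raised for malformed trees or label mismatches."""


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree (path or Newick string) with branch lengths."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick", rooting="default-rooted")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is not None and edge.length < 0:
            raise TreeError("negative branch length in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def vcv_matrix(
    tree: dendropy.Tree, order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic variance–covariance matrix of a rooted tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths.
    order : sequence of str, optional
        Tip order for the rows/columns; defaults to the tree's leaf order.

    Returns
    -------
    V : (n, n) ndarray
        Shared branch-length matrix; ``V[i, i]`` is the root-to-tip distance.
    labels : list of str
        Tip labels in row order.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if order is not None:
        missing = set(order) - set(labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(set(order)) != len(order):
            raise TreeError("duplicate labels in requested order")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # single postorder pass: depth at each internal node is the covariance of
    # every cross-child tip pair beneath it.  A root (stem) edge, as left by
    # pruning, is shared history of all tips and preserves root-to-tip depth.
    depth: dict[int, float] = {id(tree.seed_node): tree.seed_node.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depth[id(node)]
            tipsets[id(node)] = np.array([i])
        else:
            children = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia, ib = children[a], children[b]
                    V[np.ix_(ia, ib)] = d
                    V[np.ix_(ib, ia)] = d
            tipsets[id(node)] = np.concatenate(children)

    if order is not None:
        idx = [index[lab] for lab in order]
        V = V[np.ix_(idx, idx)]
        labels = list(order)
    return V, labels


def pagel_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled by ``lam``, diagonal kept.

    ``lam=1`` returns ``V`` unchanged (Brownian motion); ``lam=0`` returns
    ``diag(V)`` (a star phylogeny, phylogenetic independence).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise TreeError("V must be square")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def prune_tree(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; unifurcations collapsed, path lengths kept.

    Root-to-tip distances of retained tips are preserved because collapsed
    degree-2 nodes have their branch lengths summed.
    """
    keep = list(keep)
    present = set(tip_labels(tree))
    unknown = [k for k in keep if k not in present]
    if unknown:
        raise TreeError(f"labels not in tree: {unknown}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    # extract_tree keeps the original root edge; harmless for VCV purposes
    return pruned


def independent_contrasts(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> np.ndarray:
    """Felsenstein's standardized independent contrasts.

    One contrast per internal node of a bifurcating tree:
    ``(x1 - x2) / sqrt(v1 + v2)`` with the usual pruning-algorithm branch
    length corrections.  Polytomies are resolved by combining children
    sequentially (zero-length internal edges), matching the convention of
    multichotomy-tolerant implementations.
    """
    missing = [lab for lab in tip_labels(tree) if lab not in trait]
    if missing:
        raise TreeError(f"trait missing for tips: {missing}")

    contrasts: list[float] = []
    state: dict[int, tuple[float, float]] = {}  # node -> (value, working edge len)
    for node in tree.postorder_node_iter():
        edge_len = node.edge.length or 0.0
        if node.is_leaf():
            state[id(node)] = (float(trait[node.taxon.label]), edge_len)
            continue
        vals = [state.pop(id(c)) for c in node.child_nodes()]
        x1, v1 = vals[0]
        for x2, v2 in vals[1:]:
            if v1 + v2 <= 0:
                raise TreeError("zero-length sister pair: contrast undefined")
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            x1 = (x1 * v2 + x2 * v1) / (v1 + v2)
            v1 = (v1 * v2) / (v1 + v2)
        state[id(node)] = (x1, v1 + edge_len)
    return np.asarray(contrasts)
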