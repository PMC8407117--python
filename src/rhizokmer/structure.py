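"""Clonal population-structure correction.

Near-identical genomes carry almost no independent information about a
genotype-phenotype association, so treating them as independent samples
inflates test statistics.  The correction used here follows the classic
sequence-weighting recipe: build an ultrametric dendrogram of the strains
by UPGMA on their pairwise k-mer Jaccard distances, then derive
Gerstein-Sonnhammer-Chothia (GSC) weights by distributing each branch
length among the leaves below it.  Clones end up sharing the weight a
single strain would have carried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode


@dataclass
class StrainTree:
    """Rooted ultrametric dendrogram over strains.

    ``tree`` is a skbio TreeNode whose leaves are strain ids and whose
    branch lengths derive from UPGMA merge heights (height = distance/2).
    """

    tree: TreeNode
    heights: dict[int, float]  # id(node) -> height above the leaves

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def node_height(self, node: TreeNode) -> float:
        return self.heights[id(node)]

    def is_ultrametric(self, atol: float = 1e-9) -> bool:
        depths = [self.tree.distance(t) for t in self.tree.tips()]
        return bool(np.ptp(depths) <= atol) if depths else True

    def to_newick(self) -> str:
        return str(self.tree).strip()

    def write(self, path) -> None:
        self.tree.write(str(path), format="newick")


def upgma(dist: pd.DataFrame) -> StrainTree:
    """Average-linkage agglomeration with deterministic tie-breaking.

    At each step the pair of clusters at minimal distance is merged at
    height d/2 (so root-to-leaf depths are equal).  Ties are broken by
    the lowest pair of original strain indices, compared as
    (min representative index, max representative index).
    """
    labels = list(dist.index)
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two strains")

    heights: dict[int, float] = {}
    nodes: dict[int, TreeNode] = {}
    size: dict[int, int] = {}
    rep: dict[int, int] = {}  # smallest original index in the cluster
    active = list(range(n))
    dmat = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    for i in range(n):
        leaf = TreeNode(name=labels[i])
        nodes[i] = leaf
        heights[id(leaf)] = 0.0
        size[i] = 1
        rep[i] = i
    height_of: dict[int, float] = {i: 0.0 for i in range(n)}
    next_id = n
    while len(active) > 1:
        best = None
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                i, j = active[a], active[b]
                key = (dmat[(min(i, j), max(i, j))],
                       min(rep[i], rep[j]), max(rep[i], rep[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dij, _, _), i, j = best
        h = dij / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - height_of[i]
        right.length = h - height_of[j]
        parent = TreeNode(children=[left, right])
        heights[id(parent)] = h
        nid = next_id
        next_id += 1
        nodes[nid] = parent
        height_of[nid] = h
        size[nid] = size[i] + size[j]
        rep[nid] = min(rep[i], rep[j])
        for m in active:
            if m in (i, j):
                continue
            dim = dmat[(min(i, m), max(i, m))]
            djm = dmat[(min(j, m), max(j, m))]
            dmat[(min(nid, m), max(nid, m))] = (
                size[i] * dim + size[j] * djm) / (size[i] + size[j])
        active = [m for m in active if m not in (i, j)] + [nid]
    root = nodes[active[0]]
    root.length = None
    return StrainTree(tree=root, heights=heights)


def gsc_weights(tree: StrainTree, normalize: bool = True) -> pd.Series:
    """Gerstein-Sonnhammer-Chothia leaf weights from an ultrametric tree.

    Each leaf starts with its terminal branch length.  Walking rootward,
    every internal node's parent-edge length is split among its
    descendant leaves in proportion to their accumulated weights
    (equally when all are still zero, e.g. among exact clones).  Weights
    are finally scaled to sum to the number of leaves, so equal-weight
    data reduce downstream tests to their unweighted form.
    """
    leaves = list(tree.tree.tips())
    names = [t.name for t in leaves]
    w = {}
    for t in leaves:
        ln = t.length or 0.0
        if ln < 0:
            raise ValueError(f"negative branch length at leaf {t.name!r}")
        w[t.name] = float(ln)
    # internal nodes processed leaves-to-root (postorder guarantees
    # children first)
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            continue
        ln = node.length or 0.0
        if ln < 0:
            raise ValueError("negative internal branch length")
        if ln == 0:
            continue
        below = [t.name for t in node.tips()]
        tot = sum(w[b] for b in below)
        if tot == 0:
            for b in below:
                w[b] += ln / len(below)
        else:
            for b in below:
                w[b] += ln * w[b] / tot
    out = pd.Series([w[nm] for nm in names], index=names, dtype=float)
    if normalize:
        s = out.sum()
        if s == 0:
            out[:] = 1.0  # star of clones: everyone equal
        else:
            out = out * (len(names) / s)
    return out
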