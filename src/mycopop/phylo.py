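"""Genotype distances and neighbor-joining phylogeny.

The distance is the allele-sharing dosage distance
d(i, j) = mean_l |g_il - g_jl| / 2, which is 0 for identical strains and 1
for opposite homozygotes at every locus.  The tree is built with the
Saitou-Nei neighbor-joining algorithm (authored here, with a deterministic
lexicographic tie-break so results are reproducible); trees are scikit-bio
``TreeNode`` objects and serialize to Newick.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core import MISSING, GenotypeMatrix

__all__ = [
    "genotype_distance",
    "neighbor_joining",
    "root_with_outgroup",
    "bootstrap_support",
    "bipartitions",
]


def genotype_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distance over dosage genotypes.

    Missing calls at a locus drop that locus from the pair's average.
    """
    d = matrix.dosages.astype(float)
    d[matrix.dosages == MISSING] = np.nan
    n = matrix.n_strains
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[i] - d[i + 1 :]) / 2.0
        out[i, i + 1 :] = np.nanmean(diff, axis=1) if diff.size else 0.0
    out = out + out.T
    return DistanceMatrix(out, ids=list(matrix.strains))


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei NJ on a distance matrix; returns an unrooted tree.

    Joins are chosen by the standard Q criterion; exact Q ties are broken by
    the lexicographically smallest (sorted) taxon-pair of the nodes' current
    labels, making the topology independent of input order.  Negative branch
    lengths (possible on non-additive inputs) are clamped to zero with a
    warning.
    """
    ids = list(dist.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = np.asarray(dist.data, dtype=float).copy()
    # nodes: (sort key, TreeNode) — key is the smallest tip label in the clade
    nodes: list[tuple[str, TreeNode]] = [(i, TreeNode(name=i)) for i in ids]
    clamped = False

    def _set_length(node: TreeNode, length: float) -> bool:
        node.length = max(length, 0.0)
        return length < 0

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i][0], nodes[j][0])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        key_i, node_i = nodes[i]
        key_j, node_j = nodes[j]
        clamped |= _set_length(node_i, li)
        clamped |= _set_length(node_j, lj)
        parent = TreeNode(children=[node_i, node_j])
        new_d = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D_new = np.zeros((n - 1, n - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = new_d[keep]
        D = D_new
        nodes = [nodes[k] for k in keep] + [(min(key_i, key_j), parent)]

    # resolve the final three around an (unrooted) internal node
    (ka, a), (kb, b), (kc, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        clamped |= _set_length(node, length)
    root = TreeNode(children=[a, b, c])
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return root


def root_with_outgroup(tree: TreeNode, taxon: str) -> TreeNode:
    """Root the tree on the outgroup's pendant edge (at its midpoint)."""
    try:
        tip = tree.find(taxon)
    except Exception as exc:
        raise ValueError(f"outgroup {taxon!r} not found in tree") from exc
    if not tip.is_tip():
        raise ValueError(f"outgroup {taxon!r} is not a leaf")
    return tree.root_at(tip, above=True)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as its smaller tip side."""
    taxa = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


def bootstrap_support(
    matrix: GenotypeMatrix,
    tree: TreeNode,
    n_replicates: int = 100,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Clade support by locus resampling.

    Loci are resampled with replacement ``n_replicates`` times; each
    replicate's NJ tree is reduced to its bipartitions, and support for each
    bipartition of the reference tree is the fraction of replicates that
    recover it.
    """
    rng = np.random.default_rng(seed)
    ref_splits = bipartitions(tree)
    counts = {s: 0 for s in ref_splits}
    for _ in range(n_replicates):
        idx = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        rep_tree = neighbor_joining(genotype_distance(matrix.take_loci(idx)))
        rep_splits = bipartitions(rep_tree)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: c / n_replicates for s, c in counts.items()}
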