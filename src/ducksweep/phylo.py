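"""Individual-level p-distances, neighbor-joining trees and bootstrap support.

The p-distance between two diploid individuals is the allele-sharing
distance: sum of |dosage_i - dosage_j| over jointly genotyped sites, divided
by twice the number of such sites — the proportion of differing allele
copies, in [0, 1].  Trees are built with Saitou & Nei's neighbor-joining on
that matrix (deterministic smallest-label tie-breaking) and serialised as
Newick; branch support comes from resampling SNP columns with replacement
and counting recovered leaf bipartitions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variant_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def p_distance_matrix(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise allele-sharing p-distance between all samples.

    Sites where either sample is missing are excluded pairwise; a pair with
    zero jointly genotyped sites is an error.
    """
    if gm.n_samples < 3:
        raise ValueError("p_distance_matrix needs >= 3 samples")
    return _p_distance_from_dosages(gm.dosages, gm.samples)


def _p_distance_from_dosages(dosages: np.ndarray, samples: list[str]) -> tuple[list[str], np.ndarray]:
    d = dosages.astype(np.float64)
    d[dosages == MISSING] = np.nan
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no genotyped sites"
                )
            dist = np.abs(d[ok, i] - d[ok, j]).sum() / (2.0 * m)
            out[i, j] = out[j, i] = dist
    return list(samples), out


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted tree stored with an arbitrary internal root."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (rooted at a trifurcation for storage) over sample labels."""

    root: TreeNode
    labels: list[str]

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.10g}" for child, length in node.children
            )
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}"

        return fmt(self.root) + ";"

    def write(self, path, with_support: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick(with_support=with_support) + "\n")

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (tree metric induced by the branch lengths)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        leaf_ids: dict[str, int] = {}

        def walk(node: TreeNode) -> int:
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf:
                leaf_ids[node.name] = nid
            for child, length in node.children:
                cid = walk(child)
                adj[nid].append((cid, length))
                adj[cid].append((nid, length))
            return nid

        walk(self.root)
        labels = [l for l in self.labels if l in leaf_ids]
        n = len(labels)
        out = np.zeros((n, n))
        for i, lab in enumerate(labels):
            # Dijkstra is overkill on a tree; simple DFS accumulation
            dist = {leaf_ids[lab]: 0.0}
            stack = [leaf_ids[lab]]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, lab2 in enumerate(labels):
                out[i, j] = dist[leaf_ids[lab2]]
        return labels, out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (internal edges), normalised to the
        side not containing the first label."""
        n = len(self.labels)
        ref = self.labels[0]
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                child_set = walk(child)
                if 2 <= len(child_set) <= n - 2:
                    parts.add(
                        child_set
                        if ref not in child_set
                        else frozenset(self.labels) - child_set
                    )
                below = below | child_set
            return below

        walk(self.root)
        return parts

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for child, _ in node.children:
                    walk(child)

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels: list[str], distances: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the lexicographically smallest pair of cluster
    keys (a cluster's key is its smallest leaf label), making the result
    deterministic.  Negative branch-length estimates are clamped to zero
    with the deficit moved to the sibling edge, conserving the joined pair's
    path length.  For an additive input matrix the tree metric reproduces
    the input exactly.
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix has a nonzero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    keys: list[str] = list(labels)
    D = D.copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12) & (Q <= qmin + 1e-12))
        best = min(
            (tuple(sorted((keys[i], keys[j]))), (min(i, j), max(i, j)))
            for i, j in cand
            if i < j
        )[1]
        i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d_ij - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three clusters join at the central node (three-point formulas)
    (a, b, c) = nodes
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = d_ab - la
    lc = d_ac - la
    clamped = [max(x, 0.0) for x in (la, lb, lc)]
    if any(x < 0 for x in (la, lb, lc)):
        log.info("nj_tree: clamped negative terminal branch length(s) to 0")
    root = TreeNode(children=[(a, clamped[0]), (b, clamped[1]), (c, clamped[2])])
    return PhyloTree(root=root, labels=list(labels))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    gm: GenotypeMatrix,
    n_replicates: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree with internal-edge bootstrap supports (percent of replicates).

    Each replicate resamples SNP columns with replacement, recomputes the
    p-distance matrix and the NJ tree, and scores which leaf bipartitions of
    the full-data tree reappear (topology only).  Seeded and reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if gm.n_samples < 4:
        raise ValueError("bootstrap support needs >= 4 samples (no internal edges otherwise)")
    labels, D = p_distance_matrix(gm)
    tree = nj_tree(labels, D)
    # map each internal node to its normalised bipartition
    n = len(labels)
    ref = labels[0]
    node_part: dict[int, frozenset[str]] = {}

    def walk(node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below = below | walk(child)
        if node is not tree.root and 2 <= len(below) <= n - 2:
            node_part[id(node)] = (
                below if ref not in below else frozenset(labels) - below
            )
        return below

    walk(tree.root)

    counts: dict[frozenset[str], int] = {p: 0 for p in node_part.values()}
    rng = np.random.default_rng(seed)
    n_sites = gm.n_sites
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        _, D_rep = _p_distance_from_dosages(gm.dosages[cols], labels)
        rep_parts = nj_tree(labels, D_rep).bipartitions()
        for p in counts:
            if p in rep_parts:
                counts[p] += 1

    def assign(node) -> None:
        if not node.is_leaf:
            if id(node) in node_part:
                node.support = 100.0 * counts[node_part[id(node)]] / n_replicates
            for child, _ in node.children:
                assign(child)

    assign(tree.root)
    return tree
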