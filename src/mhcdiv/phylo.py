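"""Neighbor-joining trees, column-bootstrap supports, outgroup rooting.

The agglomeration is the Saitou-Nei criterion
``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` with ties broken
by the smallest (i, j) index pair, branch lengths by the standard
formulas (negative estimates clamped to zero and counted), and exact
recovery of additive matrices.  Trees are :class:`dendropy.Tree` objects
throughout, so Newick round-tripping, rerooting and MRCA queries use
dendropy's machinery.

Bootstrap supports resample alignment columns with replacement, rebuild
the distance matrix and tree per replicate, and score each internal edge
of the original tree by the percentage of replicates containing the same
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "nj",
    "bipartitions",
    "bootstrap_support",
    "BootstrapResult",
    "root_on_outgroup",
    "read_newick",
    "write_newick",
]


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix (>= 3 taxa).

    The returned tree is unrooted (trifurcating seed node).  The number
    of branch lengths clamped from negative estimates to zero is stored
    on the tree as ``tree.nj_clamped``.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = np.array(dm.values, dtype=float)
    if D.min() < 0:
        raise ValueError("distance matrix has negative entries")

    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)

    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q = np.minimum(Q, Q.T)  # guard against last-ulp asymmetry
        qmin = Q.min()
        ii, jj = np.nonzero(Q == qmin)
        pairs = sorted({(min(int(a), int(b)), max(int(a), int(b))) for a, b in zip(ii, jj)})
        i, j = pairs[0]
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        du = (D[i] + D[j] - D[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = du[keep]
        D_new[:-1, -1] = du[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-node star with closed-form branch lengths
    root = dendropy.Node()
    (a, b, c) = (0, 1, 2)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    for k, lk in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = clamp(lk)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    tree.nj_clamped = clamped
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each internal edge is represented canonically by the side NOT
    containing the alphabetically first leaf label, so rooted and
    unrooted representations of the same tree compare equal.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    full = frozenset(labels)
    ref = labels[0]
    n = len(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = _leafset(node)
        if len(side) < 2 or len(side) > n - 2:
            continue
        out.add(full - side if ref in side else side)
    return out


@dataclass
class BootstrapResult:
    """NJ tree with internal-edge supports from column bootstrapping."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_skipped: int


def bootstrap_support(
    labels: Sequence[str],
    seqs: Sequence[str],
    distance_fn: Callable[[Sequence[str], Sequence[str]], DistanceMatrix],
    n_reps: int = 1000,
    seed: int = 0,
    min_support_shown: float | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap over alignment columns.

    ``distance_fn(labels, seqs)`` must rebuild a :class:`DistanceMatrix`
    for each resampled alignment.  Replicates in which all sequences are
    identical (degenerate distance matrix) are skipped and counted;
    supports are percentages over the non-degenerate replicates.  When
    ``min_support_shown`` is given, smaller supports are left blank in
    the tree's internal-node labels (the convention of showing only
    supports above 50 in published figures) while the full support map is
    always returned.
    """
    base_dm = distance_fn(labels, seqs)
    tree = nj(base_dm)
    orig = bipartitions(tree)
    counts = {b: 0 for b in orig}

    rng = np.random.default_rng(seed)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )
    L = arr.shape[1]
    skipped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        sub = arr[:, idx]
        if (sub == sub[0]).all():
            skipped += 1
            continue
        rseqs = [row.tobytes().decode("ascii") for row in sub]
        rep_biparts = bipartitions(nj(distance_fn(labels, rseqs)))
        for b in orig:
            if b in rep_biparts:
                counts[b] += 1

    effective = n_reps - skipped
    supports = {
        b: (100.0 * c / effective if effective else 0.0) for b, c in counts.items()
    }

    # annotate internal nodes of the original tree
    labels_sorted = sorted(labels)
    full = frozenset(labels_sorted)
    ref = labels_sorted[0]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        canon = full - side if ref in side else side
        sup = supports.get(canon)
        if sup is None:
            continue
        if min_support_shown is not None and sup < min_support_shown:
            node.label = None
        else:
            node.label = f"{sup:.0f}"
    return BootstrapResult(
        tree=tree, supports=supports, n_replicates=n_reps, n_skipped=skipped
    )


def root_on_outgroup(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup leaf's edge."""
    node = tree.find_node_with_taxon_label(label)
    if node is None:
        raise KeyError(f"outgroup label {label!r} not found in tree")
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def read_newick(path_or_string: str, from_path: bool = False) -> dendropy.Tree:
    src = {"path": path_or_string} if from_path else {"data": path_or_string}
    return dendropy.Tree.get(schema="newick", **src)


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
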