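"""Relative-rate divergence dating on a rooted tree with one calibration.

A deliberately simple relative-rate scheme stands in for full
maximum-likelihood relative-time estimation: lineage rates are read off
branch lengths bottom-up, assuming sister clades subtend the same amount
of time.  For a node ``u`` let ``ell(u)`` be the leaf-count-weighted mean
path length from ``u`` to its descendant leaves.  The root lineage is
assigned rate 1; a child lineage ``c`` of ``u`` inherits
``rate(c) = rate(u) * (e_c + ell(c)) / ell(u)`` (its clade's mean depth
relative to its siblings'), and the node's relative time is
``t(u) = ell(u) / rate(u)``.  On ultrametric input this reproduces node
depths exactly; rescaling all branch lengths leaves the normalised
relative times unchanged; and times decrease monotonically from root to
leaves (strictly, when branch lengths are positive).

One calibration — an MRCA identified by a pair of leaf labels plus an
age in Mya — converts relative times to absolute ages by a single global
scalar.  Because branch lengths here come from distance trees rather
than ML optimisation, absolute dates are indicative (ordering and rough
magnitude), not point estimates with credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = ["TimeTree", "relative_times", "calibrate"]


@dataclass
class TimeTree:
    """Rooted tree whose nodes carry relative (and, once calibrated,
    absolute) times; leaves are at time 0, the root is maximal."""

    tree: dendropy.Tree
    calibration: tuple[tuple[str, str], float] | None = None

    def _node_time(self, node: dendropy.Node, attr: str) -> float:
        value = getattr(node, attr, None)
        if value is None:
            raise ValueError("tree has not been dated; run relative_times/calibrate")
        return value

    def mrca(self, leaf_a: str, leaf_b: str) -> dendropy.Node:
        node = self.tree.mrca(taxon_labels=[leaf_a, leaf_b])
        if node is None:
            raise KeyError(f"no MRCA found for {leaf_a!r}, {leaf_b!r}")
        return node

    def relative_time(self, leaf_a: str, leaf_b: str) -> float:
        """Relative time (root = 1) of the MRCA of two leaves."""
        return self._node_time(self.mrca(leaf_a, leaf_b), "time_rel")

    def age(self, leaf_a: str, leaf_b: str) -> float:
        """Calibrated age in Mya of the MRCA of two leaves."""
        return self._node_time(self.mrca(leaf_a, leaf_b), "age_mya")

    def table(self) -> pd.DataFrame:
        """One row per internal node: identifying leaf pair, times."""
        rows = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            first = sorted(l.taxon.label for l in children[0].leaf_iter())[0]
            second = sorted(l.taxon.label for l in children[-1].leaf_iter())[0]
            rows.append(
                {
                    "leaf_a": first,
                    "leaf_b": second,
                    "n_leaves": sum(1 for _ in node.leaf_iter()),
                    "time_rel": getattr(node, "time_rel", float("nan")),
                    "age_mya": getattr(node, "age_mya", float("nan")),
                }
            )
        return pd.DataFrame(rows)


def relative_times(tree: dendropy.Tree) -> TimeTree:
    """Assign relative node times to a rooted tree with branch lengths.

    Polytomies are handled by the same weighted averaging (no arbitrary
    resolution is required by the rate recursion).  A root clade of total
    depth zero cannot be dated.
    """
    if not tree.is_rooted:
        raise ValueError("relative_times requires a rooted tree")

    # bottom-up: leaf counts and weighted mean depths
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_leaves = 1
            node._ell = 0.0
        else:
            children = node.child_nodes()
            node._n_leaves = sum(c._n_leaves for c in children)
            node._ell = (
                sum(c._n_leaves * ((c.edge.length or 0.0) + c._ell) for c in children)
                / node._n_leaves
            )

    root = tree.seed_node
    if root._ell <= 0:
        raise ValueError("tree has zero total depth; cannot assign times")

    # top-down: lineage rates and raw times
    root._rate = 1.0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node._time_raw = 0.0
            continue
        node._time_raw = node._ell / node._rate
        for c in node.child_nodes():
            span = (c.edge.length or 0.0) + c._ell
            c._rate = node._rate * (span / node._ell) if span > 0 else node._rate

    t_root = root._time_raw
    for node in tree.preorder_node_iter():
        node.time_raw = node._time_raw
        node.time_rel = node._time_raw / t_root
        for attr in ("_n_leaves", "_ell", "_rate", "_time_raw"):
            if hasattr(node, attr):
                delattr(node, attr)
    return TimeTree(tree=tree)


def calibrate(
    tt: TimeTree, node_spec: tuple[str, str], age_mya: float
) -> TimeTree:
    """Convert relative times to absolute ages via one calibration.

    ``node_spec`` is a pair of leaf labels whose MRCA is pinned to
    ``age_mya``; every node's age becomes
    ``time_rel * age_mya / time_rel(calibration node)``.
    """
    if age_mya <= 0:
        raise ValueError("calibration age must be positive")
    cal_rel = tt.relative_time(*node_spec)
    if cal_rel <= 0:
        raise ValueError("calibration node has relative time 0")
    scale = age_mya / cal_rel
    for node in tt.tree.preorder_node_iter():
        node.age_mya = node.time_rel * scale
    tt.calibration = (tuple(node_spec), age_mya)
    return tt
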