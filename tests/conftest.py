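"""Shared fixtures and independent oracle helpers for the test suite.

The helpers here deliberately avoid the package's own code paths: tree
distances come from shortest paths on an explicit edge graph, topology
search is exhaustive, and translation uses biopython's codon tables —
so they can serve as independent oracles for the implementation.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# Random additive trees as edge graphs (oracle side)
# ---------------------------------------------------------------------------


def random_additive_graph(n_leaves: int, rng: np.random.Generator) -> nx.Graph:
    """Random unrooted binary tree with leaf nodes 0..n-1 and positive
    branch lengths, built by sequential random addition."""
    g = nx.Graph()
    nxt = [n_leaves]  # next internal node id

    def new_internal() -> int:
        nxt[0] += 1
        return nxt[0] - 1

    center = new_internal()
    for leaf in range(3):
        g.add_edge(leaf, center, weight=float(rng.uniform(0.5, 2.0)))
    for leaf in range(3, n_leaves):
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(v, mid, weight=w * (1.0 - split))
        g.add_edge(leaf, mid, weight=float(rng.uniform(0.5, 2.0)))
    return g


def graph_distance_matrix(g: nx.Graph, n_leaves: int) -> np.ndarray:
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(n_leaves):
            D[i, j] = dist[i][j]
    return D


def graph_bipartitions(g: nx.Graph, labels: list[str]) -> set[frozenset[str]]:
    """Non-trivial splits of the tree graph, canonicalised like the
    implementation: the side not containing the first sorted label."""
    n = len(labels)
    ref = sorted(labels)[0]
    full = frozenset(labels)
    out: set[frozenset[str]] = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        side_nodes = nx.node_connected_component(h, u)
        side = frozenset(labels[k] for k in side_nodes if k < n)
        if len(side) < 2 or len(side) > n - 2:
            continue
        out.add(full - side if ref in side else side)
    return out


# ---------------------------------------------------------------------------
# Exhaustive five-taxon topology search (least-squares oracle)
# ---------------------------------------------------------------------------


def five_taxon_topologies() -> list[nx.Graph]:
    """All 15 unrooted binary topologies on leaves 0..4 (unit weights)."""
    base = nx.Graph()
    base.add_edges_from([(0, 5), (1, 5), (2, 5)])
    trees3 = [base]
    trees = []
    for t3 in trees3:
        for u, v in list(t3.edges()):
            t4 = t3.copy()
            t4.remove_edge(u, v)
            t4.add_edges_from([(u, 6), (v, 6), (3, 6)])
            for a, b in list(t4.edges()):
                t5 = t4.copy()
                t5.remove_edge(a, b)
                t5.add_edges_from([(a, 7), (b, 7), (4, 7)])
                trees.append(t5)
    # deduplicate by bipartition signature
    seen = {}
    for t in trees:
        labels = [str(i) for i in range(5)]
        for u, v in t.edges():
            t[u][v]["weight"] = 1.0
        sig = frozenset(graph_bipartitions(t, labels))
        seen.setdefault(sig, t)
    return list(seen.values())


def least_squares_topology(D: np.ndarray) -> set[frozenset[str]]:
    """Bipartitions of the best least-squares fit among all 15
    five-taxon topologies (branch lengths by unconstrained lstsq)."""
    labels = [str(i) for i in range(5)]
    pairs = list(itertools.combinations(range(5), 2))
    d = np.array([D[i, j] for i, j in pairs])
    best = None
    for tree in five_taxon_topologies():
        edges = list(tree.edges())
        A = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            path = nx.shortest_path(tree, i, j)
            on_path = {frozenset(e) for e in zip(path, path[1:])}
            for col, e in enumerate(edges):
                if frozenset(e) in on_path:
                    A[row, col] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(((A @ x - d) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, graph_bipartitions(tree, labels))
    return best[1]


# ---------------------------------------------------------------------------
# Genetic-code oracle (biopython-backed, independent of the package table)
# ---------------------------------------------------------------------------


def bio_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def bio_is_stop(codon: str) -> bool:
    return bio_translate(codon) == "*"


def enumerate_site_counts(codon: str) -> tuple[float, float]:
    """Exhaustive single-neighbour enumeration of NG86 site counts."""
    s = n = 0.0
    for pos in range(3):
        syn = non = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if bio_is_stop(alt):
                continue
            if bio_translate(alt) == bio_translate(codon):
                syn += 1
            else:
                non += 1
        s += syn / (syn + non)
        n += non / (syn + non)
    return s, n


def enumerate_pathways(ca: str, cb: str) -> tuple[float, float]:
    """Brute-force (Sd, Nd): average over all stop-free mutational
    pathways between two sense codons."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(positions):
        cur = ca
        s = n = 0
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if bio_is_stop(nxt):
                ok = False
                break
            if bio_translate(nxt) == bio_translate(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            results.append((s, n))
    if not results:
        return float("nan"), float("nan")
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (read-only)."""
    from mhcdiv import synth

    return synth.simulate(synth.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sense_codons():
    from mhcdiv.codon_selection import SENSE_CODONS

    return SENSE_CODONS
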