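"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's search code: the RING oracle is eight
explicit nested loops over ligand-class index lists, the motif oracle checks
every window position by position, and the phylogeny oracles work on explicit
edge graphs (random additive trees, exhaustive topology enumeration with
least-squares branch fitting).
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def build_domain(gaps=(2, 14, 2, 2, 2, 10, 2), ligands="CCCHHCCC",
                 filler="A"):
    """A RING domain string with given inter-ligand gaps; returns (seq,
    ligand offsets)."""
    parts, offsets, pos = [], [], 0
    for i, lig in enumerate(ligands):
        parts.append(lig)
        offsets.append(pos)
        pos += 1
        if i < len(gaps):
            parts.append(filler * gaps[i])
            pos += gaps[i]
    return "".join(parts), tuple(offsets)


# ---------------------------------------------------------------------------
# RING grammar oracle
# ---------------------------------------------------------------------------

def brute_ring_placements(seq, profile):
    """Every 8-tuple of ligand-class residues with all 7 gaps in range."""
    idx = [[i for i, a in enumerate(seq) if a in cls]
           for cls in profile.ligand_classes]
    sp = profile.spacing

    def ok(a, b, k):
        return sp[k][0] <= b - a - 1 <= sp[k][1]

    out = []
    for p0 in idx[0]:
        for p1 in idx[1]:
            if not ok(p0, p1, 0):
                continue
            for p2 in idx[2]:
                if not ok(p1, p2, 1):
                    continue
                for p3 in idx[3]:
                    if not ok(p2, p3, 2):
                        continue
                    for p4 in idx[4]:
                        if not ok(p3, p4, 3):
                            continue
                        for p5 in idx[5]:
                            if not ok(p4, p5, 4):
                                continue
                            for p6 in idx[6]:
                                if not ok(p5, p6, 5):
                                    continue
                                for p7 in idx[7]:
                                    if ok(p6, p7, 6):
                                        out.append((p0, p1, p2, p3,
                                                    p4, p5, p6, p7))
    return out


def brute_resolve(placements, profile):
    """The spec's overlap rule, restated: leftmost start, then minimal total
    insert, then position tuple; chosen hits share no ligand position."""
    def insert_sum(t):
        return sum(abs((t[i + 1] - t[i] - 1) - profile.canonical_spacing[i])
                   for i in range(7))

    picked, used = [], set()
    for t in sorted(placements, key=lambda t: (t[0], insert_sum(t), t)):
        if not (used & set(t)):
            picked.append(t)
            used |= set(t)
    return picked


# ---------------------------------------------------------------------------
# motif oracle
# ---------------------------------------------------------------------------

def brute_motif_hits(seq, pattern, budget):
    """(start, mismatches) for every window within the mismatch budget."""
    L = len(pattern.positions)
    out = []
    for start in range(len(seq) - L + 1):
        mism = sum(1 for k, allowed in enumerate(pattern.positions)
                   if allowed is not None and seq[start + k] not in allowed)
        if mism <= budget:
            out.append((start, mism))
    return out


# ---------------------------------------------------------------------------
# phylogeny oracles
# ---------------------------------------------------------------------------

def random_additive_tree(n, rng):
    """Random unrooted binary tree with branch lengths in [0.1, 1.0].

    Returns (graph, leaf names); leaves are 'L0'..'L{n-1}'.
    """
    leaves = [f"L{i}" for i in range(n)]
    g = nx.Graph()
    g.add_edges_from(("c0", leaf) for leaf in leaves[:3])
    for k, leaf in enumerate(leaves[3:], start=1):
        u, v = sorted(g.edges())[rng.integers(0, g.number_of_edges())]
        w = f"c{k}"
        g.remove_edge(u, v)
        g.add_edges_from([(u, w), (w, v), (w, leaf)])
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
    return g, leaves


def leaf_distance_matrix(g, leaves):
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = dist[leaves[i]][leaves[j]]
    return (D + D.T) / 2.0  # exact symmetry despite float summation order


def graph_splits(g, leaves):
    """Non-trivial bipartitions of an unrooted tree graph, canonicalized as
    the side not containing the smallest leaf name."""
    ref = min(leaves)
    leafset = set(leaves)
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(nx.node_connected_component(h, u) & leafset)
        if len(side) < 2 or len(leafset - side) < 2:
            continue
        splits.add(frozenset(leafset - side) if ref in side else side)
    return splits


def enumerate_topologies(leaves):
    """All unrooted binary topologies over the leaves, as edge graphs."""
    leaves = list(leaves)
    g0 = nx.Graph()
    g0.add_edges_from(("c0", leaf) for leaf in leaves[:3])
    tops = [g0]
    for k, leaf in enumerate(leaves[3:], start=1):
        grown = []
        for g in tops:
            for u, v in sorted(g.edges()):
                h = g.copy()
                w = f"c{k}"
                h.remove_edge(u, v)
                h.add_edges_from([(u, w), (w, v), (w, leaf)])
                grown.append(h)
        tops = grown
    return tops


def fit_branch_lengths(g, leaves, D):
    """Least-squares branch lengths for a topology against a distance matrix.

    Returns (lengths dict, max residual); an additive exact fit has residual
    ~0 and nonnegative lengths.
    """
    edges = sorted(g.edges())
    eidx = {frozenset(e): k for k, e in enumerate(edges)}
    rows, rhs = [], []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            path = nx.shortest_path(g, leaves[i], leaves[j])
            row = np.zeros(len(edges))
            for u, v in zip(path, path[1:]):
                row[eidx[frozenset((u, v))]] = 1.0
            rows.append(row)
            rhs.append(D[i, j])
    A = np.array(rows)
    b = np.array(rhs)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.max(np.abs(A @ x - b)))
    return {tuple(e): x[k] for k, e in enumerate(edges)}, residual
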