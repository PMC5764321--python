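"""Distance-based grouping of RING domains.

Full multiple alignment is unnecessary for this domain: the eight metal
ligands are obligate anchor columns, so domains align exactly by fixing the
ligand columns and right-padding each inter-ligand spacer with gaps to the
widest spacer observed.  Pairwise p-distances (pairwise deletion over gapped
columns) or their Poisson correction feed a standard Neighbor-Joining
agglomeration with seeded column-bootstrap supports, and query leaves are
assigned to reference groups by nearest anchor along tree paths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix

from .ring_grammar import RingDomainHit

logger = logging.getLogger(__name__)

GAP = "-"


# ---------------------------------------------------------------------------
# anchored alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchoredAlignment:
    """Equal-length rows over 8 fixed ligand columns + padded spacer blocks."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])


def anchor_align(hits: Sequence[RingDomainHit],
                 seqs: Mapping[str, str]) -> AnchoredAlignment:
    """Align RING domains on their ligand positions.

    ``seqs`` maps protein id -> full sequence.  Removing gap characters from
    any row recovers the input domain (ligand 1 through ligand 8) exactly.
    """
    if len(hits) < 2:
        raise ValueError("anchored alignment needs at least 2 domains")
    n_lig = {len(h.ligand_positions) for h in hits}
    if len(n_lig) != 1:
        raise ValueError("hits use incompatible ligand-class schemes: "
                         f"{sorted(n_lig)} ligand counts")
    k = n_lig.pop()
    widths = [max(h.spacing[i] for h in hits) for i in range(k - 1)]
    ids, rows = [], []
    for h in hits:
        seq = seqs[h.protein_id]
        pos = h.ligand_positions
        parts = []
        for i in range(k - 1):
            parts.append(seq[pos[i]])
            spacer = seq[pos[i] + 1:pos[i + 1]]
            parts.append(spacer.ljust(widths[i], GAP))
        parts.append(seq[pos[-1]])
        ids.append(h.protein_id)
        rows.append("".join(parts))
    return AnchoredAlignment(ids=tuple(ids), rows=tuple(rows))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distances(aln: AnchoredAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion p-distance, optionally Poisson-corrected.

    Columns where either row carries a gap are skipped per pair; the Poisson
    model applies d = −ln(1 − p).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    arr = np.array([list(r) for r in aln.rows])
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (arr[i] != GAP) & (arr[j] != GAP)
            m = int(usable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]!r} and "
                    f"{aln.ids[j]!r}")
            p = float((arr[i][usable] != arr[j][usable]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 between {aln.ids[i]!r} and "
                        f"{aln.ids[j]!r}: Poisson correction undefined")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=list(aln.ids))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent (None at the root)."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.warning("negative branch length %.6g at %s clamped to 0",
                       length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Standard Q-criterion Neighbor-Joining.

    Ties in Q are broken by the smallest (i, j) index pair in the current
    working order; negative branch lengths are clamped to zero with a warning.
    The result is an unrooted tree serialized with a degree-3 root (degree-2
    for two taxa, where the single edge is split at an anonymous midpoint).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if np.any(dm.data < 0):
        raise ValueError("distance matrix has negative entries")
    D = dm.data.astype(float).copy()
    nodes: list[Node] = [Node(name=i) for i in ids]

    if n == 2:
        half = D[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return Node(children=nodes)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q:  # strict: ties keep the earlier (i, j)
                    best_q, best = q, (i, j)
        i, j = best
        vi = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        nodes[i].length = _clamp(vi, f"join({i},{j})")
        nodes[j].length = _clamp(vj, f"join({i},{j})")
        new = Node(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = _clamp((dab + dac - dbc) / 2.0, "final")
    b.length = _clamp((dab + dbc - dac) / 2.0, "final")
    c.length = _clamp((dac + dbc - dab) / 2.0, "final")
    return Node(children=[a, b, c])


def tree_splits(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side that does not
    contain the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        splits.add(all_leaves - side if ref in side else side)
    return splits


def path_lengths(tree: Node) -> "dict[tuple[str, str], float]":
    """Leaf-to-leaf path lengths via the tree's edge graph (networkx)."""
    import networkx as nx

    g = nx.Graph()
    counter = [0]

    def add(node: Node, parent_key) -> None:
        key = node.name if node.is_leaf() else f"__int{counter[0]}"
        counter[0] += 1
        if parent_key is not None:
            g.add_edge(parent_key, key, weight=node.length or 0.0)
        else:
            g.add_node(key)
        for c in node.children:
            add(c, key)

    add(tree, None)
    leaves = tree.leaf_names()
    out: dict[tuple[str, str], float] = {}
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for a in leaves:
        for b in leaves:
            out[(a, b)] = lengths[a][b]
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: AnchoredAlignment, n_reps: int, seed: int,
                      model: str = "p") -> Node:
    """NJ tree with per-edge supports from seeded column resampling.

    Support for an internal edge is the fraction of replicate trees containing
    its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(distances(aln, model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    L = aln.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = tuple("".join(r[c] for c in cols) for r in aln.rows)
        rep_aln = AnchoredAlignment(ids=aln.ids, rows=rows)
        try:
            rep_tree = neighbor_joining(distances(rep_aln, model))
        except ValueError:
            # a pathological resample (e.g. all-gap columns for a pair)
            # contributes support to no split
            continue
        for s in tree_splits(rep_tree):
            if s in counts:
                counts[s] += 1

    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        key = all_leaves - side if ref in side else side
        if key in counts:
            node.support = counts[key] / n_reps
    return tree


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def assign_groups(tree: Node, anchors: Mapping[str, Sequence[str]],
                  margin_ratio: float = 0.1,
                  outlier_group: str = "H") -> dict[str, str]:
    """Assign every leaf to the group of its nearest anchor by path length.

    ``anchors`` maps group name -> reference leaf ids.  A query whose nearest
    anchors from two different groups are nearly equidistant — relative margin
    (d2 − d1)/d2 below ``margin_ratio`` — lacks clear affinity and goes to the
    outlier group.
    """
    if not anchors or not any(anchors.values()):
        raise ValueError("anchor set is empty")
    anchor_group = {aid: g for g, aids in anchors.items() for aid in aids}
    leaves = set(tree.leaf_names())
    missing = set(anchor_group) - leaves
    if missing:
        raise ValueError(f"anchor ids not in tree: {sorted(missing)}")

    dist = path_lengths(tree)
    result: dict[str, str] = {}
    for leaf in sorted(leaves):
        if leaf in anchor_group:
            result[leaf] = anchor_group[leaf]
            continue
        per_group = {
            g: min(dist[(leaf, aid)] for aid in aids)
            for g, aids in anchors.items() if aids}
        ranked = sorted(per_group.items(), key=lambda kv: (kv[1], kv[0]))
        g1, d1 = ranked[0]
        if d1 == 0.0 or len(ranked) == 1:
            result[leaf] = g1
            continue
        d2 = ranked[1][1]
        margin = (d2 - d1) / d2 if d2 > 0 else 0.0
        result[leaf] = outlier_group if margin < margin_ratio else g1
    return result
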