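import numpy as np
import pytest
from skbio import DistanceMatrix

from ctlscan import phylo_grouping as pg
from ctlscan.io_formats import newick_string
from ctlscan.ring_grammar import builtin_profiles, scan_ring_domains
from oracles import build_domain

CANON = builtin_profiles()["canonical"]


def _hits(domain_specs):
    """RING hits + seq map for a set of (id, gaps, filler) domain specs."""
    hits, seqs = [], {}
    for pid, gaps, filler in domain_specs:
        seq, _ = build_domain(gaps=gaps, filler=filler)
        from ctlscan.io_formats import ProteinRecord
        rec = ProteinRecord(id=pid, seq=seq, lineage="plant")
        profile = CANON if gaps == (2, 14, 2, 2, 2, 10, 2) else \
            CANON.widened(1, min(g for g in (gaps[1], 14)),
                          max(gaps[1], 14))
        (h,) = scan_ring_domains(rec, profile)
        hits.append(h)
        seqs[pid] = rec.seq
    return hits, seqs


CANON_GAPS = (2, 14, 2, 2, 2, 10, 2)


class TestAnchorAlign:
    def test_identical_domains_align_without_gaps(self):
        hits, seqs = _hits([("a", CANON_GAPS, "A"), ("b", CANON_GAPS, "A")])
        aln = pg.anchor_align(hits, seqs)
        assert aln.rows[0] == aln.rows[1]
        assert "-" not in aln.rows[0]

    def test_shorter_spacer_padded_with_one_gap(self):
        wide = (2, 15, 2, 2, 2, 10, 2)
        hits, seqs = _hits([("a", CANON_GAPS, "A"), ("b", wide, "A")])
        aln = pg.anchor_align(hits, seqs)
        assert aln.rows[0].count("-") == 1
        assert aln.rows[1].count("-") == 0
        assert len(aln.rows[0]) == len(aln.rows[1])

    def test_degapped_row_recovers_domain(self):
        wide = (2, 15, 2, 2, 2, 10, 2)
        hits, seqs = _hits([("a", CANON_GAPS, "D"), ("b", wide, "E")])
        for h, row in zip(hits, pg.anchor_align(hits, seqs).rows):
            domain = seqs[h.protein_id][h.start:h.end]
            assert row.replace("-", "") == domain

    def test_single_hit_errors(self):
        hits, seqs = _hits([("a", CANON_GAPS, "A")])
        with pytest.raises(ValueError, match="at least 2"):
            pg.anchor_align(hits, seqs)


class TestDistances:
    def test_p_distance_one_diff_in_four(self):
        aln = pg.AnchoredAlignment(ids=("a", "b"), rows=("ACDE", "ACDF"))
        assert pg.distances(aln, "p")["a", "b"] == pytest.approx(0.25)

    def test_poisson_correction(self):
        aln = pg.AnchoredAlignment(ids=("a", "b"), rows=("ACDE", "ACDF"))
        d = pg.distances(aln, "poisson")["a", "b"]
        assert d == pytest.approx(0.287682, abs=1e-6)

    def test_identical_rows_distance_zero(self):
        aln = pg.AnchoredAlignment(ids=("a", "b"), rows=("ACDE", "ACDE"))
        assert pg.distances(aln)["a", "b"] == 0.0

    def test_gapped_columns_pairwise_deleted(self):
        aln = pg.AnchoredAlignment(ids=("a", "b"), rows=("AC-E", "ACDE"))
        assert pg.distances(aln)["a", "b"] == 0.0

    def test_no_comparable_columns_errors(self):
        aln = pg.AnchoredAlignment(ids=("a", "b"), rows=("A--", "-CC"))
        with pytest.raises(ValueError, match="comparable"):
            pg.distances(aln)

    def test_unknown_model_rejected(self):
        aln = pg.AnchoredAlignment(ids=("a", "b"), rows=("AC", "AC"))
        with pytest.raises(ValueError, match="model"):
            pg.distances(aln, "jtt")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                            ids=["A", "B", "C"])
        tree = pg.neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == {"A": pytest.approx(1), "B": pytest.approx(1),
                           "C": pytest.approx(3)}

    def test_four_taxon_additive_split_and_lengths(self):
        # tree ((A:1,B:1):1,(C:1,D:1)) -> dAB=dCD=2, cross distances 4
        D = np.array([[0, 2, 4, 4], [2, 0, 4, 4],
                      [4, 4, 0, 2], [4, 4, 2, 0]], float)
        dm = DistanceMatrix(D, ids=list("ABCD"))
        tree = pg.neighbor_joining(dm)
        assert pg.tree_splits(tree) == {frozenset({"C", "D"})}
        pl = pg.path_lengths(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert pl[(a, b)] == pytest.approx(D[i, j], abs=1e-9)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        tree = pg.neighbor_joining(dm)
        assert pg.path_lengths(tree)[("A", "B")] == pytest.approx(2.0)
        assert newick_string(tree) == "(A:1.000000,B:1.000000);"

    def test_asymmetric_matrix_rejected_at_construction(self):
        from skbio.stats.distance import DistanceMatrixError

        with pytest.raises(DistanceMatrixError):
            DistanceMatrix([[0, 1], [2, 0]], ids=["A", "B"])

    def test_negative_entries_rejected(self):
        from types import SimpleNamespace

        dm = SimpleNamespace(ids=["A", "B", "C"],
                             data=np.array([[0.0, -1.0, 1.0],
                                            [-1.0, 0.0, 1.0],
                                            [1.0, 1.0, 0.0]]))
        with pytest.raises(ValueError, match="negative"):
            pg.neighbor_joining(dm)

    def test_agrees_with_skbio_nj_on_random_matrix(self):
        from skbio.tree import nj

        rng = np.random.default_rng(23)
        n = 6
        ids = [f"t{i}" for i in range(n)]
        M = rng.uniform(0.2, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(D, ids=ids)
        ours = pg.neighbor_joining(dm)
        theirs = nj(dm)
        our_splits = pg.tree_splits(ours)
        ref = min(ids)
        their_splits = set()
        all_ids = frozenset(ids)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                their_splits.add(all_ids - side if ref in side else side)
        assert our_splits == their_splits


class TestBootstrap:
    def _separated_alignment(self):
        # two clades: identical within, very different between
        return pg.AnchoredAlignment(
            ids=("a1", "a2", "b1", "b2"),
            rows=("AAAAAAAAAA", "AAAAAAAAAA", "WWWWWWWWWW", "WWWWWWWWWW"))

    def test_clean_separation_gets_full_support(self):
        for seed in (0, 1, 99):
            tree = pg.bootstrap_support(self._separated_alignment(),
                                        n_reps=25, seed=seed)
            supports = [n.support for n in tree.walk()
                        if n.support is not None]
            assert supports and all(s == 1.0 for s in supports)

    def test_supports_bounded(self):
        aln = pg.AnchoredAlignment(
            ids=("a", "b", "c", "d"),
            rows=("ACDEFGHIKL", "ACDEFGHIKV", "ACDEFGHIRL", "ACDEFGWIKL"))
        tree = pg.bootstrap_support(aln, n_reps=30, seed=4)
        for n in tree.walk():
            if n.support is not None:
                assert 0.0 <= n.support <= 1.0

    def test_same_seed_reproducible(self):
        aln = pg.AnchoredAlignment(
            ids=("a", "b", "c", "d"),
            rows=("ACDEFGHIKL", "ACDEFGHIKV", "ACDEFGHIRL", "ACDEFGWIKL"))
        t1 = pg.bootstrap_support(aln, n_reps=20, seed=8)
        t2 = pg.bootstrap_support(aln, n_reps=20, seed=8)
        assert newick_string(t1) == newick_string(t2)


class TestAssignGroups:
    def _tree(self, leaves):
        return pg.Node(children=[pg.Node(name=n, length=l)
                                 for n, l in leaves])

    def test_zero_distance_leaf_gets_anchor_group(self):
        tree = self._tree([("anchorA", 0.0), ("q", 0.0), ("anchorB", 2.0)])
        groups = pg.assign_groups(tree, {"A": ["anchorA"], "B": ["anchorB"]})
        assert groups["q"] == "A"

    def test_equidistant_leaf_goes_to_outlier_group(self):
        tree = self._tree([("anchorA", 1.0), ("q", 1.0), ("anchorB", 1.0)])
        groups = pg.assign_groups(tree, {"A": ["anchorA"], "B": ["anchorB"]})
        assert groups["q"] == "H"

    def test_clear_margin_assigns_nearest_group(self):
        tree = self._tree([("anchorA", 0.1), ("q", 0.1), ("anchorB", 5.0)])
        groups = pg.assign_groups(tree, {"A": ["anchorA"], "B": ["anchorB"]})
        assert groups["q"] == "A"

    def test_anchors_only_identity(self):
        tree = self._tree([("a", 1.0), ("b", 1.0), ("c", 1.0)])
        groups = pg.assign_groups(tree, {"A": ["a"], "B": ["b"],
                                         "C": ["c"]})
        assert groups == {"a": "A", "b": "B", "c": "C"}

    def test_empty_anchor_set_errors(self):
        tree = self._tree([("a", 1.0), ("b", 1.0)])
        with pytest.raises(ValueError, match="empty"):
            pg.assign_groups(tree, {})

    def test_unknown_anchor_id_errors(self):
        tree = self._tree([("a", 1.0), ("b", 1.0)])
        with pytest.raises(ValueError, match="not in tree"):
            pg.assign_groups(tree, {"A": ["zz"]})
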