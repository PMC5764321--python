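import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctlscan import ring_grammar as rg
from oracles import brute_resolve, brute_ring_placements, build_domain


class TestProfiles:
    def test_builtin_set(self, profiles):
        assert set(profiles) == {"canonical", "fungal", "kinetoplast",
                                 "ciliate"}
        assert profiles["canonical"].canonical_spacing == (2, 14, 2, 2, 2,
                                                           10, 2)

    def test_fungal_ranges_are_canonical_plus_one_at_g2_g6(self, profiles):
        f = profiles["fungal"]
        assert f.spacing[1] == (15, 15)
        assert f.spacing[5] == (11, 11)

    def test_invalid_range_rejected(self):
        with pytest.raises(rg.ProfileError, match="min <= max"):
            rg.LineageProfile("bad", rg.CANONICAL_LIGAND_CLASSES,
                              ((2, 1),) + ((2, 2),) * 6,
                              rg.CANONICAL_SPACING)

    def test_wrong_ligand_count_rejected(self):
        with pytest.raises(rg.ProfileError, match="8 ligand"):
            rg.LineageProfile("bad", rg.CANONICAL_LIGAND_CLASSES[:7],
                              ((2, 2),) * 7, rg.CANONICAL_SPACING)


class TestScan:
    def test_canonical_domain_single_hit(self, canonical):
        seq, offsets = build_domain()
        hits = rg.scan_ring_domains(seq, canonical)
        assert len(hits) == 1
        h = hits[0]
        assert h.ligand_positions == offsets
        assert h.variant == "RING-H2"
        assert h.spacing == (2, 14, 2, 2, 2, 10, 2)
        assert h.inserts == (0,) * 7

    def test_fungal_inserts_at_g2_and_g6(self, profiles):
        seq, _ = build_domain(gaps=(2, 15, 2, 2, 2, 11, 2))
        (h,) = rg.scan_ring_domains(seq, profiles["fungal"])
        assert h.inserts == (0, 1, 0, 0, 0, 1, 0)

    @pytest.mark.parametrize("extra,n_hits", [(26, 1), (27, 0)])
    def test_kinetoplast_insert_bound(self, profiles, extra, n_hits):
        seq, _ = build_domain(gaps=(2, 14 + extra, 2, 2, 2, 10, 2))
        assert len(rg.scan_ring_domains(seq, profiles["kinetoplast"])) \
            == n_hits

    def test_no_ligands_no_hits(self, canonical):
        assert rg.scan_ring_domains("A" * 100, canonical) == []

    def test_short_sequence_yields_empty_list(self, canonical):
        assert rg.scan_ring_domains("CACH", canonical) == []

    def test_x_never_satisfies_a_ligand_class(self, canonical):
        seq, _ = build_domain()
        broken = "X" + seq[1:]
        assert rg.scan_ring_domains(broken, canonical) == []

    def test_determinism(self, canonical):
        seq, _ = build_domain()
        seq = "M" * 7 + seq + seq  # two domains
        assert (rg.scan_ring_domains(seq, canonical)
                == rg.scan_ring_domains(seq, canonical))

    def test_two_tandem_domains_both_reported(self, canonical):
        seq, offsets = build_domain()
        hits = rg.scan_ring_domains(seq + "GG" + seq, canonical)
        assert len(hits) == 2
        shift = len(seq) + 2
        assert hits[1].ligand_positions == tuple(p + shift for p in offsets)


class TestVariant:
    def test_his_at_ligand5_is_ring_h2(self, canonical):
        seq, offsets = build_domain(ligands="CCCHHCCC")
        assert rg.classify_variant(offsets, seq) == "RING-H2"

    def test_cys_at_ligand5_is_ring_hc(self, canonical):
        seq, offsets = build_domain(ligands="CCCHCCCC")
        (h,) = rg.scan_ring_domains(seq, canonical)
        assert h.variant == "RING-HC"

    def test_other_residue_is_a_contract_violation(self):
        seq, offsets = build_domain(ligands="CCCHACCC")
        with pytest.raises(ValueError, match="C or H"):
            rg.classify_variant(offsets, seq)


class TestDiagnostics:
    def _domain_with(self, substitutions):
        seq, offsets = build_domain()
        chars = list(seq)
        for pos, aa in substitutions:
            chars[pos] = aa
        return "".join(chars), offsets

    def test_atl_rule_set_fires(self):
        # Leu after ligand 2, Arg four before ligand 3, Asp after ligand 6
        _, off = self._domain_with([])
        seq, off = self._domain_with([(off[1] + 1, "L"), (off[2] - 4, "R"),
                                      (off[5] + 1, "D")])
        d = rg.match_diagnostics(off, seq)
        assert (d.atl_L_at_lig2p1, d.atl_R_at_lig3m4, d.atl_D_at_lig6p1) \
            == (True, True, True)
        assert d.btl_P_at_lig6p2 is False
        assert d.atl_flag_count == 3

    def test_btl_proline_fires_alone(self):
        _, off = self._domain_with([])
        seq, off = self._domain_with([(off[5] + 2, "P")])
        d = rg.match_diagnostics(off, seq)
        assert d.btl_P_at_lig6p2 is True
        assert d.atl_flag_count == 0

    @pytest.mark.parametrize("offset,expected", [
        (-1, "adjacent"), (-2, "separated_by_one")])
    def test_proline_near_ligand3(self, offset, expected):
        _, off = self._domain_with([])
        seq, off = self._domain_with([(off[2] + offset, "P")])
        assert rg.match_diagnostics(off, seq).pro_adjacent_lig3 == expected

    def test_proline_absent(self):
        seq, off = self._domain_with([])
        assert rg.match_diagnostics(off, seq).pro_adjacent_lig3 == "absent"


class TestOracleEquivalence:
    """The DFS scanner must agree with an explicit nested-loop enumeration."""

    @pytest.mark.parametrize("profile_name", ["canonical", "kinetoplast"])
    def test_random_sequences(self, profiles, profile_name):
        profile = profiles[profile_name]
        rng = np.random.default_rng(42)
        letters = list("CH" * 4 + "ADEFGIKLMNPQRSTVWY")  # ligand-enriched
        for _ in range(40):
            n = int(rng.integers(30, 201))
            seq = "".join(rng.choice(letters, size=n))
            expected = brute_resolve(brute_ring_placements(seq, profile),
                                     profile)
            got = [h.ligand_positions
                   for h in rg.scan_ring_domains(seq, profile)]
            assert got == expected

    def test_planted_domain_recovered(self, profiles):
        rng = np.random.default_rng(7)
        for name, profile in profiles.items():
            gaps = tuple(int(rng.integers(lo, hi + 1))
                         for lo, hi in profile.spacing)
            seq, offsets = build_domain(gaps=gaps)
            hits = rg.scan_ring_domains("MGGDE" + seq, profile)
            assert [h.ligand_positions for h in hits] \
                == [tuple(p + 5 for p in offsets)], name


@settings(max_examples=30, deadline=None, derandomize=True)
@given(gap_index=st.integers(0, 6), widen=st.integers(1, 5),
       seed=st.integers(0, 10_000))
def test_widening_a_spacing_range_never_removes_hits(gap_index, widen, seed):
    profile = rg.builtin_profiles()["canonical"]
    rng = np.random.default_rng(seed)
    letters = list("CH" * 4 + "ADEFGIKLMNPQRSTVWY")
    seq = "".join(rng.choice(letters, size=120))
    before = {h.ligand_positions
              for h in rg.scan_ring_domains(seq, profile)}
    lo, hi = profile.spacing[gap_index]
    wide = profile.widened(gap_index, max(lo - widen, 0), hi + widen)
    after_all = set(rg._enumerate_placements(seq, wide))
    assert before <= after_all  # every old placement remains valid
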