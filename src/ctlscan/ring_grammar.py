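"""RING-domain detection as a position grammar over eight metal ligands.

A RING zinc finger is defined here operationally: eight Cys/His residues
(numbered 1–8 from the N-terminus) whose seven inter-ligand gaps each fall in a
lineage-specific range.  A His at ligand 5 makes the domain RING-H2, a Cys
makes it RING-HC.  Family-diagnostic residues are read off at fixed offsets
relative to the ligands: ATL domains carry Leu one residue after ligand 2, Arg
four residues before ligand 3 and Asp one residue after ligand 6; BTL domains
carry Pro two residues after ligand 6; and many domains carry a conserved Pro
immediately upstream of ligand 3.

Lineage profiles encode the spacing deviations seen in different taxa: fungal
domains carry exactly one extra residue in gaps 2–3 and 6–7; kinetoplastid and
ciliate domains tolerate up to twenty-six extra residues between ligands 2
and 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: canonical inter-ligand gaps g1..g7 (residues strictly between ligands)
CANONICAL_SPACING = (2, 14, 2, 2, 2, 10, 2)

#: ligand residue classes 1..8 (C3-H-[H/C]-C3); position 5 admits both
#: variants, and the matched residue decides RING-H2 vs RING-HC
CANONICAL_LIGAND_CLASSES = tuple(
    frozenset(s) for s in ("C", "C", "C", "H", "CH", "C", "C", "C"))


class ProfileError(ValueError):
    """Raised when a lineage profile violates its invariants."""


@dataclass(frozen=True)
class LineageProfile:
    """Ligand classes and inter-ligand spacing ranges for one taxon class."""

    name: str
    ligand_classes: tuple[frozenset[str], ...]
    spacing: tuple[tuple[int, int], ...]
    canonical_spacing: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ligand_classes) != 8:
            raise ProfileError(f"{self.name}: need 8 ligand classes")
        if len(self.spacing) != 7 or len(self.canonical_spacing) != 7:
            raise ProfileError(f"{self.name}: need 7 spacing ranges and "
                               "7 canonical gaps")
        for k, (lo, hi) in enumerate(self.spacing):
            if not 0 <= lo <= hi:
                raise ProfileError(
                    f"{self.name}: spacing range g{k + 1} must satisfy "
                    f"0 <= min <= max, got ({lo}, {hi})")
            if self.canonical_spacing[k] < 0:
                raise ProfileError(
                    f"{self.name}: canonical gap g{k + 1} must be >= 0")
            # note: ranges may sit entirely above the canonical gap — that is
            # how lineage-specific inserts (fungal +1, kinetoplastid +1..26)
            # are expressed

    def min_span(self) -> int:
        """Shortest sequence length a match can occupy."""
        return 8 + sum(lo for lo, _ in self.spacing)

    def widened(self, gap_index: int, lo: int, hi: int) -> "LineageProfile":
        """Copy with one spacing range replaced (used for what-if scans)."""
        spacing = list(self.spacing)
        spacing[gap_index] = (lo, hi)
        return LineageProfile(self.name, self.ligand_classes, tuple(spacing),
                              self.canonical_spacing)


def _exact_ranges(gaps: Sequence[int]) -> tuple[tuple[int, int], ...]:
    return tuple((g, g) for g in gaps)


def builtin_profiles() -> dict[str, LineageProfile]:
    """The shipped lineage profiles.

    canonical   — plants, vertebrates, invertebrates: gaps (2,14,2,2,2,10,2).
    fungal      — one extra residue in gap 2 and gap 6 exactly.
    kinetoplast — gap 2 stretches to canonical+26; otherwise canonical.
    ciliate     — same tolerance as kinetoplast.
    """
    canon = LineageProfile("canonical", CANONICAL_LIGAND_CLASSES,
                           _exact_ranges(CANONICAL_SPACING), CANONICAL_SPACING)
    fungal_gaps = list(CANONICAL_SPACING)
    fungal_gaps[1] += 1
    fungal_gaps[5] += 1
    fungal = LineageProfile("fungal", CANONICAL_LIGAND_CLASSES,
                            _exact_ranges(fungal_gaps), CANONICAL_SPACING)
    kine_spacing = list(_exact_ranges(CANONICAL_SPACING))
    kine_spacing[1] = (CANONICAL_SPACING[1] + 1, CANONICAL_SPACING[1] + 26)
    kinetoplast = LineageProfile("kinetoplast", CANONICAL_LIGAND_CLASSES,
                                 tuple(kine_spacing), CANONICAL_SPACING)
    ciliate = LineageProfile("ciliate", CANONICAL_LIGAND_CLASSES,
                             tuple(kine_spacing), CANONICAL_SPACING)
    return {p.name: p for p in (canon, fungal, kinetoplast, ciliate)}


#: lineage tag -> profile name used when scanning a proteome
LINEAGE_TO_PROFILE = {
    "plant": "canonical",
    "vertebrate": "canonical",
    "invertebrate": "canonical",
    "fungus": "fungal",
    "kinetoplast": "kinetoplast",
    "ciliate": "ciliate",
    "other": "canonical",
}


def profile_for_lineage(lineage: str,
                        profiles: dict[str, LineageProfile] | None = None
                        ) -> LineageProfile:
    profiles = profiles or builtin_profiles()
    return profiles[LINEAGE_TO_PROFILE.get(lineage, "canonical")]


# ---------------------------------------------------------------------------
# hits and diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticReport:
    """Family-diagnostic residues read at ligand-relative offsets."""

    atl_L_at_lig2p1: bool
    atl_R_at_lig3m4: bool
    atl_D_at_lig6p1: bool
    btl_P_at_lig6p2: bool
    pro_adjacent_lig3: str  # "adjacent" | "separated_by_one" | "absent"

    @property
    def atl_flag_count(self) -> int:
        return sum((self.atl_L_at_lig2p1, self.atl_R_at_lig3m4,
                    self.atl_D_at_lig6p1))


@dataclass(frozen=True)
class RingDomainHit:
    """One placement of the eight-ligand grammar on a protein."""

    protein_id: str
    ligand_positions: tuple[int, ...]
    variant: str  # "RING-H2" | "RING-HC"
    spacing: tuple[int, ...]
    inserts: tuple[int, ...]
    profile_name: str
    diagnostics: DiagnosticReport

    @property
    def start(self) -> int:
        return self.ligand_positions[0]

    @property
    def end(self) -> int:
        """0-based half-open end (position after ligand 8)."""
        return self.ligand_positions[-1] + 1


def classify_variant(ligand_positions: Sequence[int], seq: str) -> str:
    """RING-H2 if ligand 5 is His, RING-HC if Cys; anything else is a bug."""
    aa = seq[ligand_positions[4]]
    if aa == "H":
        return "RING-H2"
    if aa == "C":
        return "RING-HC"
    raise ValueError(
        f"residue {aa!r} at ligand position 5 (index {ligand_positions[4]}): "
        "grammar should only match C or H here")


def match_diagnostics(ligand_positions: Sequence[int], seq: str
                      ) -> DiagnosticReport:
    """Evaluate the ATL/BTL diagnostic residues and the ligand-3 proline."""
    def residue_is(index: int, aa: str) -> bool:
        if 0 <= index < len(seq):
            return seq[index] == aa
        logger.warning("diagnostic offset %d outside sequence", index)
        return False

    lig2, lig3, lig6 = (ligand_positions[1], ligand_positions[2],
                        ligand_positions[5])
    if residue_is(lig3 - 1, "P"):
        pro = "adjacent"
    elif residue_is(lig3 - 2, "P"):
        pro = "separated_by_one"
    else:
        pro = "absent"
    return DiagnosticReport(
        atl_L_at_lig2p1=residue_is(lig2 + 1, "L"),
        atl_R_at_lig3m4=residue_is(lig3 - 4, "R"),
        atl_D_at_lig6p1=residue_is(lig6 + 1, "D"),
        btl_P_at_lig6p2=residue_is(lig6 + 2, "P"),
        pro_adjacent_lig3=pro,
    )


# ---------------------------------------------------------------------------
# the scanner
# ---------------------------------------------------------------------------

def _enumerate_placements(seq: str, profile: LineageProfile
                          ) -> list[tuple[int, ...]]:
    """All 8-tuples of ligand-class residues with in-range gaps (DFS)."""
    n = len(seq)
    classes = profile.ligand_classes
    out: list[tuple[int, ...]] = []

    def extend(positions: list[int]) -> None:
        k = len(positions)
        if k == 8:
            out.append(tuple(positions))
            return
        lo, hi = profile.spacing[k - 1]
        base = positions[-1]
        for gap in range(lo, hi + 1):
            p = base + gap + 1
            if p >= n:
                break
            if seq[p] in classes[k]:
                positions.append(p)
                extend(positions)
                positions.pop()

    for p0 in range(n):
        if seq[p0] in classes[0]:
            extend([p0])
    return out


def total_insert(placement: Sequence[int], profile: LineageProfile) -> int:
    return sum(abs((placement[i + 1] - placement[i] - 1)
                   - profile.canonical_spacing[i]) for i in range(7))


def resolve_overlaps(placements: Iterable[tuple[int, ...]],
                     profile: LineageProfile) -> list[tuple[int, ...]]:
    """Greedy leftmost-start selection; ties by minimal total insert, then by
    position tuple; no two chosen placements share a ligand position."""
    chosen: list[tuple[int, ...]] = []
    used: set[int] = set()
    for cand in sorted(placements,
                       key=lambda t: (t[0], total_insert(t, profile), t)):
        if used.isdisjoint(cand):
            chosen.append(cand)
            used.update(cand)
    return chosen


def scan_ring_domains(record, profile: LineageProfile) -> list[RingDomainHit]:
    """Find every maximal non-overlapping RING placement in a protein.

    ``record`` needs ``.id`` and ``.seq`` attributes (a plain string is also
    accepted, with an empty id).  X never satisfies a ligand class.  A sequence
    shorter than the minimal grammar span simply yields no hits.
    """
    if isinstance(record, str):
        pid, seq = "", record
    else:
        pid, seq = record.id, record.seq
    if len(seq) < profile.min_span():
        return []
    hits = []
    for placement in resolve_overlaps(_enumerate_placements(seq, profile),
                                      profile):
        spacing = tuple(placement[i + 1] - placement[i] - 1 for i in range(7))
        inserts = tuple(spacing[i] - profile.canonical_spacing[i]
                        for i in range(7))
        hits.append(RingDomainHit(
            protein_id=pid,
            ligand_positions=placement,
            variant=classify_variant(placement, seq),
            spacing=spacing,
            inserts=inserts,
            profile_name=profile.name,
            diagnostics=match_diagnostics(placement, seq),
        ))
    return hits
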