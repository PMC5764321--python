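"""Combine RING-domain hits, diagnostics and motif hits into family calls.

The decision order mirrors how the three RING-H2 families are defined:

1. no RING-H2 domain                         -> ``none``
2. YEELL within budget, upstream of ligand 1 -> ``CTL``  (family-defining)
3. ≥ 2 of the 3 ATL diagnostic residues      -> ``ATL``
4. the BTL proline at ligand 6 + 2           -> ``BTL``
5. degraded YEELL (budget + 2) upstream      -> ``CTL-like``
6. otherwise                                 -> ``RING-H2-unclassified``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ProteinRecord
from .motif_engine import MotifHit, MotifPattern, scan_motif, yeell_pattern
from .ring_grammar import (LineageProfile, RingDomainHit, builtin_profiles,
                           profile_for_lineage, scan_ring_domains)

logger = logging.getLogger(__name__)

LABELS = ("ATL", "BTL", "CTL", "CTL-like", "RING-H2-unclassified", "none")

#: precedence when several RING hits support different labels
_LABEL_RANK = {"CTL": 0, "ATL": 1, "BTL": 2, "CTL-like": 3,
               "RING-H2-unclassified": 4}


@dataclass(frozen=True)
class ClassifyParams:
    """Tunable thresholds for family calling.

    max_mismatch        motif budget for a full CTL call (default 3 of 14).
    degraded_extra      extra budget that still earns CTL-like (default +2).
    upstream_window     max residues between motif end and ligand 1.
    atl_min_flags       how many of the 3 ATL diagnostics must fire.
    """

    max_mismatch: int = 3
    degraded_extra: int = 2
    upstream_window: int = 150
    atl_min_flags: int = 2


@dataclass(frozen=True)
class FamilyCall:
    protein_id: str
    label: str
    lineage: str = "other"
    ring_hit: RingDomainHit | None = None
    motif_hit: MotifHit | None = None
    evidence: tuple[str, ...] = ()
    gap_to_ring: int | None = None


def _upstream_motif(ring: RingDomainHit, motif_hits: Sequence[MotifHit],
                    budget: int, window: int) -> MotifHit | None:
    """Closest motif hit ending at/before ligand 1 within the gap window."""
    lig1 = ring.ligand_positions[0]
    best: MotifHit | None = None
    for m in motif_hits:
        if m.mismatches > budget:
            continue
        gap = lig1 - m.end
        if 0 <= gap <= window and (best is None or m.end > best.end
                                   or (m.end == best.end
                                       and m.mismatches < best.mismatches)):
            best = m
    return best


def _call_for_ring(record: ProteinRecord, ring: RingDomainHit,
                   motif_hits: Sequence[MotifHit],
                   params: ClassifyParams) -> FamilyCall:
    lig1 = ring.ligand_positions[0]
    d = ring.diagnostics
    evidence = [f"ring:{ring.variant}@{ring.start + 1}-{ring.end}"
                f"(profile={ring.profile_name})"]

    if ring.variant != "RING-H2":
        evidence.append("variant-not-RING-H2")
        return FamilyCall(record.id, "none", record.lineage, ring, None,
                          tuple(evidence), None)

    motif = _upstream_motif(ring, motif_hits, params.max_mismatch,
                            params.upstream_window)
    if motif is not None:
        gap = lig1 - motif.end
        evidence.append(f"yeell@{motif.start + 1}-{motif.end}"
                        f"(mismatches={motif.mismatches},gap={gap})")
        return FamilyCall(record.id, "CTL", record.lineage, ring, motif,
                          tuple(evidence), gap)

    if d.atl_flag_count >= params.atl_min_flags:
        flags = [name for name, ok in
                 (("L@lig2+1", d.atl_L_at_lig2p1),
                  ("R@lig3-4", d.atl_R_at_lig3m4),
                  ("D@lig6+1", d.atl_D_at_lig6p1)) if ok]
        evidence.append("atl-diagnostics:" + ",".join(flags))
        return FamilyCall(record.id, "ATL", record.lineage, ring, None,
                          tuple(evidence), None)

    if d.btl_P_at_lig6p2:
        evidence.append("btl-diagnostic:P@lig6+2")
        return FamilyCall(record.id, "BTL", record.lineage, ring, None,
                          tuple(evidence), None)

    degraded = _upstream_motif(ring, motif_hits,
                               params.max_mismatch + params.degraded_extra,
                               params.upstream_window)
    if degraded is not None:
        gap = lig1 - degraded.end
        evidence.append(f"degraded-yeell@{degraded.start + 1}-{degraded.end}"
                        f"(mismatches={degraded.mismatches},gap={gap})")
        return FamilyCall(record.id, "CTL-like", record.lineage, ring,
                          degraded, tuple(evidence), gap)

    evidence.append("no-motif-no-diagnostics")
    return FamilyCall(record.id, "RING-H2-unclassified", record.lineage, ring,
                      None, tuple(evidence), None)


def classify_protein(record: ProteinRecord,
                     ring_hits: Sequence[RingDomainHit],
                     motif_hits: Sequence[MotifHit],
                     params: ClassifyParams | None = None) -> FamilyCall:
    """Family call for one protein from precomputed hits.

    With several RING hits, the hit yielding the strongest label wins; ties go
    to the leftmost hit.
    """
    params = params or ClassifyParams()
    h2_hits = [h for h in ring_hits if h.variant == "RING-H2"]
    if not h2_hits:
        return FamilyCall(record.id, "none", record.lineage,
                          evidence=("no-ring-h2-hit",))
    if len(h2_hits) > 1:
        logger.info("%s: %d RING-H2 hits; choosing the most informative",
                    record.id, len(h2_hits))
    calls = [_call_for_ring(record, h, motif_hits, params) for h in h2_hits]
    return min(calls, key=lambda c: (_LABEL_RANK[c.label],
                                     c.ring_hit.start))


def classify_proteome(records: Iterable[ProteinRecord],
                      profiles: dict[str, LineageProfile] | None = None,
                      pattern: MotifPattern | None = None,
                      params: ClassifyParams | None = None
                      ) -> tuple[list[FamilyCall], pd.DataFrame]:
    """Classify every record; returns calls plus a label × lineage count table.

    The motif scan runs at the degraded budget so CTL-like evidence is
    available; the decision rules re-apply the strict budget.
    """
    params = params or ClassifyParams()
    profiles = profiles or builtin_profiles()
    pattern = pattern or yeell_pattern()
    calls: list[FamilyCall] = []
    for rec in records:
        profile = profile_for_lineage(rec.lineage, profiles)
        ring_hits = scan_ring_domains(rec, profile)
        motif_hits = scan_motif(rec, pattern,
                                params.max_mismatch + params.degraded_extra)
        calls.append(classify_protein(rec, ring_hits, motif_hits, params))
    summary = summarize_calls(calls)
    return calls, summary


def summarize_calls(calls: Sequence[FamilyCall]) -> pd.DataFrame:
    """Counts per label (rows, all six always present) and lineage (columns)."""
    if not calls:
        return pd.DataFrame(0, index=list(LABELS), columns=[], dtype=int)
    df = pd.DataFrame({"label": [c.label for c in calls],
                       "lineage": [c.lineage for c in calls]})
    table = pd.crosstab(df["label"], df["lineage"])
    return table.reindex(list(LABELS), fill_value=0)
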