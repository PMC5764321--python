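"""Readers and writers for the formats the toolkit speaks.

Protein sequences come in as FASTA (via :mod:`Bio.SeqIO`), gene models as GFF3
(via :mod:`gffutils`), configuration as YAML, and results go out as TSV and
Newick.  All coordinates are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted exactly at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard residues plus X (unknown / masked)
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: ambiguity codes silently folded into X on input
AMBIGUOUS_TO_X = {"B", "Z", "U", "J", "O"}

#: recognised taxon tags; anything else maps to "other"
LINEAGES = ("plant", "vertebrate", "invertebrate", "fungus", "kinetoplast",
            "ciliate", "other")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, optional taxon tag, normalized sequence."""

    id: str
    seq: str
    lineage: str = "other"

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        for i, aa in enumerate(self.seq):
            if aa not in ALPHABET:
                raise FormatError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {i}")

    def __len__(self) -> int:
        return len(self.seq)


Interval = tuple[int, int]  # 0-based half-open genomic interval


@dataclass(frozen=True)
class GeneModel:
    """One mRNA: exon/CDS/5'UTR segments in transcript (5'→3') order.

    Intervals are genomic 0-based half-open.  On the minus strand the lists run
    in decreasing genomic coordinate, i.e. always 5'→3' along the transcript.
    """

    gene_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, segs in (("exon", self.exons), ("CDS", self.cds),
                           ("5'UTR", self.utr5)):
            for s, e in segs:
                if e <= s:
                    raise FormatError(
                        f"{self.gene_id}: empty/inverted {name} interval {(s, e)}")

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


# ---------------------------------------------------------------------------
# coordinate conversion (the single GFF3 <-> internal boundary)
# ---------------------------------------------------------------------------

def gff_to_internal(start1: int, end1: int) -> Interval:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(iv: Interval) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return iv[0] + 1, iv[1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize_seq(rec_id: str, raw: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if any(c in AMBIGUOUS_TO_X for c in seq):
        logger.warning("record %s: ambiguous residues mapped to X", rec_id)
        seq = "".join("X" if c in AMBIGUOUS_TO_X else c for c in seq)
    return seq


def _parse_lineage(description: str) -> str:
    for token in description.split():
        if token.startswith("lineage="):
            tag = token.split("=", 1)[1].lower()
            return tag if tag in LINEAGES else "other"
    return "other"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load protein records; uppercase, strip one terminal stop, parse lineage.

    Raises :class:`FormatError` on an empty file, duplicate identifiers or
    residues outside the allowed alphabet.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize_seq(rec.id, str(rec.seq))
        records.append(ProteinRecord(id=rec.id, seq=seq,
                                     lineage=_parse_lineage(rec.description)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(r.seq), id=r.id, description=f"lineage={r.lineage}")
               for r in records]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _transcript_sort(segs: list[Interval], strand: str) -> tuple[Interval, ...]:
    return tuple(sorted(segs, reverse=(strand == "-")))


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Build one :class:`GeneModel` per mRNA from a GFF3 file.

    Exon and CDS features must carry Parent attributes linking them to an
    mRNA/transcript.  The 5'UTR is derived as the exonic region strictly 5' of
    the first CDS base in transcript orientation (explicit five_prime_UTR
    features, when present, are ignored in favour of the derivation, which is
    exact).
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    for ft in ("exon", "CDS"):
        for feat in db.features_of_type(ft):
            if "Parent" not in feat.attributes:
                raise FormatError(
                    f"{ft} feature at {feat.seqid}:{feat.start}-{feat.end} "
                    "has no Parent attribute")

    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        strand = mrna.strand
        exons = [gff_to_internal(f.start, f.end)
                 for f in db.children(mrna, featuretype="exon")]
        cds = [gff_to_internal(f.start, f.end)
               for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            raise FormatError(f"mRNA {mrna.id}: no exons")
        exon_sorted = sorted(exons)
        for s, e in sorted(cds):
            if not any(xs <= s and e <= xe for xs, xe in exon_sorted):
                raise FormatError(
                    f"mRNA {mrna.id}: CDS segment {(s, e)} outside exons")
        exons_t = _transcript_sort(exons, strand)
        cds_t = _transcript_sort(cds, strand)
        utr5 = _derive_utr5(exons_t, cds_t, strand)
        models.append(GeneModel(gene_id=mrna.id, strand=strand, exons=exons_t,
                                cds=cds_t, utr5=utr5))
    if not models:
        raise FormatError(f"no mRNA features in {path}")
    return models


def _derive_utr5(exons_t: tuple[Interval, ...], cds_t: tuple[Interval, ...],
                 strand: str) -> tuple[Interval, ...]:
    """Exonic segments strictly 5' of the first CDS base, transcript order."""
    if not cds_t:
        return ()
    utr: list[Interval] = []
    if strand == "+":
        cds_start = min(s for s, _ in cds_t)
        for s, e in exons_t:
            if e <= cds_start:
                utr.append((s, e))
            elif s < cds_start:
                utr.append((s, cds_start))
    else:
        cds_start = max(e for _, e in cds_t)  # 5'-most CDS base boundary
        for s, e in exons_t:
            if s >= cds_start:
                utr.append((s, e))
            elif e > cds_start:
                utr.append((cds_start, e))
    return tuple(utr)


def write_gff3(models: Iterable[GeneModel], path: str | Path,
               seqid: str = "chr1", source: str = "ctlscan") -> None:
    """Serialize gene models as GFF3 (gene + mRNA + exon + CDS rows)."""
    lines = ["##gff-version 3"]
    for m in models:
        span = [c for iv in m.exons for c in iv]
        g_start, g_end = min(span[::2]), max(span[1::2])
        s1, e1 = g_start + 1, g_end
        gid, mid = f"gene:{m.gene_id}", m.gene_id
        lines.append("\t".join([seqid, source, "gene", str(s1), str(e1), ".",
                                m.strand, ".", f"ID={gid}"]))
        lines.append("\t".join([seqid, source, "mRNA", str(s1), str(e1), ".",
                                m.strand, ".", f"ID={mid};Parent={gid}"]))
        for ftype, segs, phased in (("exon", m.exons, False),
                                    ("five_prime_UTR", m.utr5, False),
                                    ("CDS", m.cds, True)):
            phase = 0
            for iv in sorted(segs):
                s1, e1 = internal_to_gff(iv)
                lines.append("\t".join(
                    [seqid, source, ftype, str(s1), str(e1), ".", m.strand,
                     str(phase) if phased else ".", f"Parent={mid}"]))
        # phase column is informational here; downstream arithmetic uses CDS
        # segment boundaries only
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

HITS_COLUMNS = ["protein_id", "profile", "variant", "start", "end",
                "ligand_positions", "spacing", "inserts",
                "atl_L_at_lig2p1", "atl_R_at_lig3m4", "atl_D_at_lig6p1",
                "btl_P_at_lig6p2", "pro_adjacent_lig3"]

CALLS_COLUMNS = ["protein_id", "label", "lineage", "ring_start", "ring_end",
                 "motif_start", "motif_end", "motif_mismatches", "gap_to_ring",
                 "evidence"]


def write_hits_tsv(hits: Sequence, path: str | Path) -> None:
    """Write RING-domain hits; an empty hit list yields a header-only file."""
    import pandas as pd

    rows = []
    for h in hits:
        d = h.diagnostics
        rows.append({
            "protein_id": h.protein_id,
            "profile": h.profile_name,
            "variant": h.variant,
            "start": h.ligand_positions[0] + 1,      # 1-based inclusive out
            "end": h.ligand_positions[-1] + 1,
            "ligand_positions": ",".join(str(p + 1) for p in h.ligand_positions),
            "spacing": ",".join(map(str, h.spacing)),
            "inserts": ",".join(map(str, h.inserts)),
            "atl_L_at_lig2p1": d.atl_L_at_lig2p1,
            "atl_R_at_lig3m4": d.atl_R_at_lig3m4,
            "atl_D_at_lig6p1": d.atl_D_at_lig6p1,
            "btl_P_at_lig6p2": d.btl_P_at_lig6p2,
            "pro_adjacent_lig3": d.pro_adjacent_lig3,
        })
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: Sequence, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        r, m = c.ring_hit, c.motif_hit
        rows.append({
            "protein_id": c.protein_id,
            "label": c.label,
            "lineage": c.lineage,
            "ring_start": r.ligand_positions[0] + 1 if r else "",
            "ring_end": r.ligand_positions[-1] + 1 if r else "",
            "motif_start": m.start + 1 if m else "",
            "motif_end": m.end if m else "",
            "motif_mismatches": m.mismatches if m else "",
            "gap_to_ring": c.gap_to_ring if c.gap_to_ring is not None else "",
            "evidence": ";".join(c.evidence),
        })
    pd.DataFrame(rows, columns=CALLS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_string(tree) -> str:
    """Serialize a :class:`ctlscan.phylo_grouping.Node` tree to Newick.

    Branch lengths are printed to 6 decimals; bootstrap supports, when present,
    appear as internal-node labels.
    """
    def fmt(node) -> str:
        if not node.children:
            body = _quote(node.name)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                body += f"{node.support:g}"
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree) + ";"


def _quote(name: str | None) -> str:
    if name is None:
        return ""
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

_PROFILE_KEYS = {"name", "lineages", "ligand_classes", "spacing",
                 "canonical_spacing"}
_PATTERN_KEYS = {"name", "consensus", "core", "max_mismatch"}


def load_profiles(path: str | Path) -> list:
    """Load lineage spacing profiles from YAML; validates keys and invariants."""
    from .ring_grammar import LineageProfile

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "profiles" not in doc:
        raise FormatError("profile config must contain a top-level 'profiles' list")
    profiles = []
    for entry in doc["profiles"]:
        unknown = set(entry) - _PROFILE_KEYS
        if unknown:
            raise FormatError(
                f"unknown profile keys {sorted(unknown)}; "
                f"valid keys are {sorted(_PROFILE_KEYS)}")
        profiles.append(LineageProfile(
            name=entry["name"],
            ligand_classes=tuple(frozenset(c) for c in entry["ligand_classes"]),
            spacing=tuple((int(lo), int(hi)) for lo, hi in entry["spacing"]),
            canonical_spacing=tuple(int(x) for x in entry["canonical_spacing"]),
        ))
    return profiles


def load_patterns(path: str | Path) -> list:
    """Load degenerate motif patterns from YAML (name, consensus, core, budget)."""
    from .motif_engine import parse_consensus

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "patterns" not in doc:
        raise FormatError("pattern config must contain a top-level 'patterns' list")
    patterns = []
    for entry in doc["patterns"]:
        unknown = set(entry) - _PATTERN_KEYS
        if unknown:
            raise FormatError(
                f"unknown pattern keys {sorted(unknown)}; "
                f"valid keys are {sorted(_PATTERN_KEYS)}")
        core = entry.get("core")
        patterns.append(parse_consensus(
            entry["consensus"], name=entry["name"],
            core=(core[0] - 1, core[1]) if core else None,  # 1-based incl in YAML
            max_mismatch=int(entry.get("max_mismatch", 3))))
    return patterns
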