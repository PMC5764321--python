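"""Intron architecture of gene models and motif/splice-junction overlap.

CDS introns are the gaps between consecutive CDS segments in transcript
orientation; 5'UTR introns are the gaps between consecutive 5'UTR exonic
segments, with sizes in genomic nucleotides.  Both are strand-aware: a gene
mirrored onto the opposite strand reports the identical architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, Interval


@dataclass(frozen=True)
class ArchitectureReport:
    gene_id: str
    cds_intron_count: int
    utr5_introns: tuple[int, ...]  # sizes in nt, transcript order
    splice_in_motif: bool | None = None


def _gap_nt(a: Interval, b: Interval, strand: str) -> int:
    """Genomic nucleotides between two transcript-adjacent segments."""
    return b[0] - a[1] if strand == "+" else a[0] - b[1]


def count_introns(model: GeneModel) -> ArchitectureReport:
    """CDS intron count and 5'UTR intron sizes for one gene model."""
    cds_introns = max(len(model.cds) - 1, 0)
    utr_sizes = []
    for a, b in zip(model.utr5, model.utr5[1:]):
        gap = _gap_nt(a, b, model.strand)
        if gap > 0:
            utr_sizes.append(gap)
    return ArchitectureReport(gene_id=model.gene_id,
                              cds_intron_count=cds_introns,
                              utr5_introns=tuple(utr_sizes))


def splice_in_motif(model: GeneModel,
                    motif_protein_span: tuple[int, int]) -> bool:
    """Does a CDS splice junction fall strictly inside a motif's coding span?

    The motif span is in 0-based half-open protein coordinates; residue ``i``
    maps to CDS nucleotides ``[3i, 3i+3)``.
    """
    start, end = motif_protein_span
    nt_start, nt_end = 3 * start, 3 * end
    total = model.cds_length()
    if nt_end > total:
        raise ValueError(
            f"{model.gene_id}: motif span {motif_protein_span} extends past "
            f"the CDS ({total} nt)")
    offset = 0
    for seg_start, seg_end in model.cds[:-1]:
        offset += seg_end - seg_start
        if nt_start < offset < nt_end:
            return True
    return False


def summarize_architecture(reports: Sequence[ArchitectureReport],
                           group_map: Mapping[str, str] | None = None
                           ) -> pd.DataFrame:
    """Per-group table: gene count, 5'UTR-intron incidence, CDS-intron range.

    Genes absent from ``group_map`` fall into the "ungrouped" row.
    """
    group_map = group_map or {}
    rows = []
    for r in reports:
        rows.append({
            "group": group_map.get(r.gene_id, "ungrouped"),
            "gene_id": r.gene_id,
            "has_utr5_intron": bool(r.utr5_introns),
            "cds_introns": r.cds_intron_count,
        })
    if not rows:
        return pd.DataFrame(columns=["genes", "with_utr5_intron",
                                     "without_utr5_intron", "cds_intron_min",
                                     "cds_intron_max"])
    df = pd.DataFrame(rows)
    out = df.groupby("group").agg(
        genes=("gene_id", "count"),
        with_utr5_intron=("has_utr5_intron", "sum"),
        cds_intron_min=("cds_introns", "min"),
        cds_intron_max=("cds_introns", "max"),
    )
    out.insert(2, "without_utr5_intron", out["genes"] - out["with_utr5_intron"])
    return out.sort_index()


def architecture_table(reports: Sequence[ArchitectureReport]) -> pd.DataFrame:
    """Flat per-gene table mirroring the published intron-incidence layout."""
    return pd.DataFrame([{
        "gene_id": r.gene_id,
        "utr5_intron_sizes_nt": ",".join(map(str, r.utr5_introns)) or "no",
        "cds_introns": r.cds_intron_count,
        "splice_in_motif": ("" if r.splice_in_motif is None
                            else str(r.splice_in_motif)),
    } for r in reports], columns=["gene_id", "utr5_intron_sizes_nt",
                                  "cds_introns", "splice_in_motif"])
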