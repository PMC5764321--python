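"""Labelled synthetic proteomes and gene models with planted ground truth.

Every generated protein is assembled from known parts — random flank, an
instance of the 21-residue YEELL consensus (CTL only), a linker, and a RING-H2
domain drawn from a lineage spacing profile, with the family-diagnostic
residues planted for ATL/BTL — so the classifier's precision and recall can be
measured against exact labels without any database retrieval.

Assemblies are rejection-sampled against the scanners themselves: a flank or
linker that happens to contain a spurious RING placement (or, for non-CTL
labels, an accidental YEELL window) is re-drawn, which keeps planted
coordinates exact.  Spacer residues inside the domain are drawn from an
alphabet without Cys/His so the planted ligand positions are unambiguous.

Gene models are built from explicit exon/intron layouts; reading the written
GFF3 back and counting introns reproduces each layout exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, ProteinRecord
from .motif_engine import MotifPattern, scan_motif, yeell_pattern
from .ring_grammar import (LineageProfile, builtin_profiles,
                           scan_ring_domains)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: spacer/diagnostic alphabet: no zinc-ligand letters
AA_NO_LIGAND = "ADEFGIKLMNPQRSTVWY"

GENERATOR_LABELS = ("CTL", "ATL", "BTL", "background")

#: profile name -> lineage tag emitted on generated records
_PROFILE_TO_LINEAGE = {"canonical": "plant", "fungal": "fungus",
                       "kinetoplast": "kinetoplast", "ciliate": "ciliate"}

_MAX_ATTEMPTS = 500


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome.

    ``motif_mutation_count`` plants exactly that many mismatches at uniformly
    chosen constrained motif positions per CTL protein;
    ``motif_mutation_rate`` instead mutates each constrained position
    independently.  ``ligand_mutation_rate`` acts per metal-ligand position.
    """

    n_per_label: Mapping[str, int]
    profile_by_label: Mapping[str, str] = field(
        default_factory=lambda: {lab: "canonical" for lab in GENERATOR_LABELS})
    linker_range: tuple[int, int] = (20, 40)
    flank_range: tuple[int, int] = (60, 100)
    motif_mutation_rate: float = 0.0
    motif_mutation_count: int = 0
    ligand_mutation_rate: float = 0.0
    background_freqs: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for lab, n in self.n_per_label.items():
            if lab not in GENERATOR_LABELS:
                raise ValueError(f"unknown label {lab!r}")
            if n < 0:
                raise ValueError(f"negative count for {lab!r}")
        for rate in (self.motif_mutation_rate, self.ligand_mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")


def _sampler(freqs: Mapping[str, float] | None):
    if freqs is None:
        letters, probs = list(AA20), None
    else:
        letters = list(freqs)
        total = sum(freqs.values())
        probs = [freqs[a] / total for a in letters]

    def draw(rng: np.random.Generator, n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs))

    return draw


def _sample_motif_instance(pattern: MotifPattern, rng: np.random.Generator,
                           draw_bg) -> str:
    out = []
    for allowed in pattern.positions:
        if allowed is None:
            out.append(draw_bg(rng, 1))
        else:
            out.append(rng.choice(sorted(allowed)))
    return "".join(out)


def _sample_domain(profile: LineageProfile, rng: np.random.Generator,
                   label: str) -> tuple[str, tuple[int, ...]]:
    """A RING-H2 instance from the profile; returns (domain, ligand offsets)."""
    gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in profile.spacing]
    spacers = ["".join(rng.choice(list(AA_NO_LIGAND), size=g)) for g in gaps]
    ligands = []
    for k, cls in enumerate(profile.ligand_classes):
        if k == 4:  # variant position: His makes the domain RING-H2
            ligands.append("H")
        else:
            ligands.append(sorted(cls)[0])

    if label == "ATL":
        # Leu after ligand 2, Arg four before ligand 3, Asp after ligand 6
        spacers[1] = "L" + spacers[1][1:]
        if gaps[1] >= 5:
            # ligand3 - 4 sits at local spacer index g2 - 4
            s = spacers[1]
            spacers[1] = s[:gaps[1] - 4] + "R" + s[gaps[1] - 3:]
        spacers[5] = "D" + spacers[5][1:]
    elif label == "BTL":
        spacers[5] = spacers[5][0] + "P" + spacers[5][2:]

    parts, offsets, pos = [], [], 0
    for k in range(8):
        parts.append(ligands[k])
        offsets.append(pos)
        pos += 1
        if k < 7:
            parts.append(spacers[k])
            pos += gaps[k]
    return "".join(parts), tuple(offsets)


def _mutate_motif(motif: str, pattern: MotifPattern, spec: SyntheticSpec,
                  rng: np.random.Generator) -> str:
    constrained = [i for i, p in enumerate(pattern.positions) if p is not None]
    targets: list[int] = []
    if spec.motif_mutation_count > 0:
        k = min(spec.motif_mutation_count, len(constrained))
        targets = list(rng.choice(constrained, size=k, replace=False))
    elif spec.motif_mutation_rate > 0:
        targets = [i for i in constrained
                   if rng.random() < spec.motif_mutation_rate]
    out = list(motif)
    for i in targets:
        allowed = pattern.positions[i]
        choices = [a for a in AA_NO_LIGAND if a not in allowed]
        out[i] = rng.choice(choices)
    return "".join(out)


def _mutate_ligands(seq: list[str], ligand_positions: Sequence[int],
                    profile: LineageProfile, rate: float,
                    rng: np.random.Generator) -> None:
    for k, pos in enumerate(ligand_positions):
        if rng.random() < rate:
            choices = [a for a in AA_NO_LIGAND
                       if a not in profile.ligand_classes[k]]
            seq[pos] = rng.choice(choices)


def generate_protein(label: str, spec: SyntheticSpec,
                     rng: np.random.Generator,
                     protein_id: str | None = None,
                     profiles: dict[str, LineageProfile] | None = None,
                     pattern: MotifPattern | None = None
                     ) -> tuple[ProteinRecord, dict]:
    """One labelled protein plus its truth record (planted coordinates)."""
    if label not in GENERATOR_LABELS:
        raise ValueError(f"unknown label {label!r}")
    profiles = profiles or builtin_profiles()
    pattern = pattern or yeell_pattern()
    profile = profiles[spec.profile_by_label.get(label, "canonical")]
    lineage = _PROFILE_TO_LINEAGE.get(profile.name, "other")
    draw_bg = _sampler(spec.background_freqs)
    pid = protein_id or label

    for _ in range(_MAX_ATTEMPTS):
        flank = draw_bg(rng, int(rng.integers(*_incl(spec.flank_range))))
        linker = draw_bg(rng, int(rng.integers(*_incl(spec.linker_range))))
        if label == "background":
            extra = draw_bg(rng, 21 + profile.min_span())
            seq = flank + linker + extra
            if scan_ring_domains(seq, profile):
                continue
            rec = ProteinRecord(id=pid, seq=seq, lineage=lineage)
            return rec, {"protein_id": pid, "label": label,
                         "lineage": lineage, "motif_start": -1,
                         "motif_end": -1, "ligand_positions": "",
                         "domain_start": -1, "domain_end": -1}

        domain, offsets = _sample_domain(profile, rng, label)
        if label == "CTL":
            motif = _sample_motif_instance(pattern, rng, draw_bg)
            base = len(flank) + len(motif) + len(linker)
            seq = flank + motif + linker + domain
            motif_span = (len(flank), len(flank) + len(motif))
        else:
            motif = ""
            base = len(flank) + len(linker)
            seq = flank + linker + domain
            motif_span = (-1, -1)
        planted = tuple(base + o for o in offsets)

        hits = scan_ring_domains(seq, profile)
        if len(hits) != 1 or hits[0].ligand_positions != planted:
            continue
        if label in ("ATL", "BTL", "background"):
            accidental = [m for m in scan_motif(
                seq, pattern, pattern.max_mismatch + 2)
                if 0 <= planted[0] - m.end <= 150]
            if accidental:
                continue
        if label == "BTL" and hits[0].diagnostics.atl_flag_count >= 2:
            continue

        # apply controlled mutations after the clean assembly is verified
        out = list(seq)
        if label == "CTL" and (spec.motif_mutation_count
                               or spec.motif_mutation_rate):
            s, e = motif_span
            mutated = _mutate_motif(seq[s:e], pattern, spec, rng)
            out[s:e] = mutated
        if spec.ligand_mutation_rate > 0:
            _mutate_ligands(out, planted, profile,
                            spec.ligand_mutation_rate, rng)
        rec = ProteinRecord(id=pid, seq="".join(out), lineage=lineage)
        return rec, {"protein_id": pid, "label": label, "lineage": lineage,
                     "motif_start": motif_span[0], "motif_end": motif_span[1],
                     "ligand_positions": ",".join(map(str, planted)),
                     "domain_start": planted[0], "domain_end": planted[-1] + 1}
    raise RuntimeError(f"could not assemble a clean {label} protein in "
                       f"{_MAX_ATTEMPTS} attempts")


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def generate_proteome(spec: SyntheticSpec,
                      profiles: dict[str, LineageProfile] | None = None,
                      pattern: MotifPattern | None = None
                      ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """n records per label (deterministic for a given spec/seed) + truth table."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    truth: list[dict] = []
    for label in GENERATOR_LABELS:
        for i in range(spec.n_per_label.get(label, 0)):
            rec, t = generate_protein(label, spec, rng,
                                      protein_id=f"{label}_{i:04d}",
                                      profiles=profiles, pattern=pattern)
            records.append(rec)
            truth.append(t)
    columns = ["protein_id", "label", "lineage", "motif_start", "motif_end",
               "ligand_positions", "domain_start", "domain_end"]
    return records, pd.DataFrame(truth, columns=columns)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLayout:
    """Declarative exon/intron layout for one synthetic gene model.

    The last 5'UTR exon segment is contiguous with the first CDS segment
    (they share a genomic exon); every other listed segment is separated from
    its neighbour by the corresponding intron.
    """

    gene_id: str
    cds_exon_lengths: tuple[int, ...]
    cds_intron_lengths: tuple[int, ...] = ()
    utr5_exon_lengths: tuple[int, ...] = ()
    utr5_intron_lengths: tuple[int, ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.cds_exon_lengths:
            raise ValueError(f"{self.gene_id}: need at least one CDS segment")
        for name, lens in (("CDS exon", self.cds_exon_lengths),
                           ("CDS intron", self.cds_intron_lengths),
                           ("5'UTR exon", self.utr5_exon_lengths),
                           ("5'UTR intron", self.utr5_intron_lengths)):
            if any(x <= 0 for x in lens):
                raise ValueError(f"{self.gene_id}: nonpositive {name} length")
        if len(self.cds_intron_lengths) != len(self.cds_exon_lengths) - 1:
            raise ValueError(f"{self.gene_id}: need exactly "
                             f"{len(self.cds_exon_lengths) - 1} CDS introns")
        n_utr_introns = max(len(self.utr5_exon_lengths) - 1, 0)
        if len(self.utr5_intron_lengths) != n_utr_introns:
            raise ValueError(f"{self.gene_id}: need exactly {n_utr_introns} "
                             "5'UTR introns")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


def build_gene_model(layout: GeneLayout, start: int = 0) -> GeneModel:
    """Realize a layout as genomic intervals (plus-strand build, mirrored for
    minus-strand layouts)."""
    cursor = start
    utr_segs: list[tuple[int, int]] = []
    for i, L in enumerate(layout.utr5_exon_lengths):
        utr_segs.append((cursor, cursor + L))
        cursor += L
        if i < len(layout.utr5_exon_lengths) - 1:
            cursor += layout.utr5_intron_lengths[i]
    cds_segs: list[tuple[int, int]] = []
    for i, L in enumerate(layout.cds_exon_lengths):
        cds_segs.append((cursor, cursor + L))
        cursor += L
        if i < len(layout.cds_exon_lengths) - 1:
            cursor += layout.cds_intron_lengths[i]

    exons: list[tuple[int, int]] = []
    if utr_segs:
        exons.extend(utr_segs[:-1])
        exons.append((utr_segs[-1][0], cds_segs[0][1]))  # boundary exon
        exons.extend(cds_segs[1:])
    else:
        exons = list(cds_segs)

    if layout.strand == "-":
        span = cursor + start
        mirror = lambda iv: (span - iv[1], span - iv[0])
        exons = [mirror(iv) for iv in exons]
        cds_segs = [mirror(iv) for iv in cds_segs]
        utr_segs = [mirror(iv) for iv in utr_segs]

    return GeneModel(gene_id=layout.gene_id, strand=layout.strand,
                     exons=tuple(exons), cds=tuple(cds_segs),
                     utr5=tuple(utr_segs))


def generate_gene_models(layouts: Sequence[GeneLayout],
                         seed: int = 0) -> tuple[list[GeneModel], pd.DataFrame]:
    """Coordinate-consistent gene models, spread along one chromosome, plus a
    truth table of the intended intron architecture."""
    rng = np.random.default_rng(seed)
    models, truth = [], []
    cursor = 1000
    for layout in layouts:
        cursor += int(rng.integers(100, 500))
        model = build_gene_model(layout, start=cursor)
        cursor = max(e for _, e in model.exons) + 100
        models.append(model)
        truth.append({
            "gene_id": layout.gene_id,
            "cds_introns": len(layout.cds_intron_lengths),
            "utr5_intron_sizes_nt": ",".join(
                map(str, layout.utr5_intron_lengths)),
        })
    return models, pd.DataFrame(truth, columns=["gene_id", "cds_introns",
                                                "utr5_intron_sizes_nt"])


def reference_layouts() -> list[GeneLayout]:
    """Layouts mirroring the published intron architectures of representative
    plant CTL genes (5'UTR intron sizes and CDS intron counts as printed;
    exon lengths, which were not published, are fixed arbitrary values)."""
    return [
        GeneLayout("ath|CTL01", cds_exon_lengths=(240, 180, 150, 120, 210),
                   cds_intron_lengths=(110, 95, 130, 88),
                   utr5_exon_lengths=(90, 75, 60),
                   utr5_intron_lengths=(235, 472)),
        GeneLayout("ath|CTL17", cds_exon_lengths=(150,) * 9,
                   cds_intron_lengths=(100, 92, 87, 120, 105, 99, 111, 84)),
        GeneLayout("ath|CTL19", cds_exon_lengths=(220, 160, 140, 130, 200),
                   cds_intron_lengths=(96, 102, 88, 76),
                   utr5_exon_lengths=(80, 70, 55),
                   utr5_intron_lengths=(82, 337)),
        GeneLayout("ath|CTL16", cds_exon_lengths=(900,)),
    ]
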