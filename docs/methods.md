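# Methods

This note records the model behind `ctlscan`, the parameters that matter, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## RING-domain grammar

A RING domain is modelled as eight metal-ligand residues with constrained
inter-ligand gaps, not as a profile HMM or PSSM.  A lineage profile consists
of

* eight ligand residue classes — `C, C, C, H, {C,H}, C, C, C`.  Ligand 5
  admits both letters; the matched residue types the variant (His → RING-H2,
  Cys → RING-HC).  `X` never satisfies a class.
* seven spacing ranges `(min_i, max_i)` for the gaps `g1..g7` (residues
  strictly between consecutive ligands), and
* seven canonical gap values used to express observed spacings as *inserts*
  (`insert_i = g_i − canonical_i`).

The canonical gap vector is (2, 14, 2, 2, 2, 10, 2).  Only `g2 = 14` is
strongly attested across lineages; `g1` and `g7` follow the universal
`C-x2-C … C-x2-C` RING consensus, and `g3–g6` are fixed values consistent
with the compact RING-H2 envelope.  All seven are per-profile configuration,
so a user with different domain statistics can override them without touching
code.  Shipped profiles:

| profile     | deviation from canonical           | used for |
|-------------|------------------------------------|----------|
| canonical   | none (exact gaps)                  | plants, vertebrates, invertebrates, unknown |
| fungal      | `g2` and `g6` each +1, exactly     | fungi |
| kinetoplast | `g2` insert 1–26 allowed           | kinetoplastids |
| ciliate     | same as kinetoplast                | ciliates |

A spacing range may sit entirely above the canonical gap — that is precisely
how lineage inserts are expressed (the fungal profile *requires* the +1, it
does not merely allow it).

**Scanning.**  All index 8-tuples satisfying the classes and ranges are
enumerated by depth-first search with gap pruning.  Overlap resolution is
greedy leftmost-start; among candidates with the same start, the one with
minimal total |insert| wins, then the lexicographically smallest position
tuple; no two reported hits share a ligand position.  This rule is
deterministic and is re-stated independently in the test oracle (explicit
nested loops), which the scanner must match exactly on random sequences.

**Diagnostics** are read at fixed ligand-relative offsets: ATL = Leu at
lig2+1, Arg at lig3−4, Asp at lig6+1; BTL = Pro at lig6+2; and the conserved
proline near ligand 3 is reported as `adjacent` (lig3−1), `separated_by_one`
(lig3−2) or `absent`.  The proline is assumed to sit on the *upstream* side
of ligand 3; a downstream placement is not treated as equivalent.  Offsets
falling outside the sequence yield a false flag and a logged warning.

## Degenerate motif engine

A motif pattern is an ordered list of positions, each an allowed-residue set
or a wildcard.  Wildcards neither match nor mismatch; an `X` in the sequence
always mismatches at a constrained position.  A window is a hit when its
mismatch count at constrained positions is within the budget; the score is
(constrained − mismatches)/constrained.  All windows are reported, including
overlaps — filtering is the classifier's job.

The shipped YEELL pattern is parsed from its 21-position consensus
(13 constrained positions, 8 wildcards; core = the 5-residue Y-E-E-L-L block
at positions 5–9).  The default budget of 3 mismatches keeps ≥ 10/13 ≈ 77% of
constrained positions matched, mirroring the ≈75% conservation that defines
the motif.  The GLD (ATL) and GLD-like (BTL) motifs were published only as
LOGO figures, so they ship as named placeholders: the engine is
pattern-agnostic and scans any user-supplied consensus.

**Chou–Fasman helix check.**  The classic rules with the published propensity
table: a 6-residue window with ≥ 4 residues of Pα > 1.03 nucleates; the
segment extends while the trailing 4-residue mean Pα ≥ 1.00; overlapping
segments merge; a merged segment is kept where mean Pα > mean Pβ.  All four
constants are module-level and overridable.  `X` is assigned Pα = Pβ = 0, so
masked residues never nucleate or extend.  A motif "sits on a helix" when a
predicted segment covers ≥ 50% of the motif window (configurable).

## Family calling

Decision order per protein (RING-H2 hits only; RING-HC never seeds a call):

1. no RING-H2 hit → `none`
2. YEELL hit within the budget, ending at or before ligand 1, gap ≤ 150
   residues → `CTL`
3. ≥ 2 of the 3 ATL diagnostics → `ATL`
4. the BTL proline → `BTL`
5. YEELL at budget + 2 upstream → `CTL-like`
6. otherwise → `RING-H2-unclassified`

CTL outranks the residue diagnostics because motif co-occurrence is the
family-defining criterion.  The 150-residue upstream window, the 2-of-3 ATL
threshold and the +2 degraded budget are explicit operational stand-ins for
judgements that were originally made by manual curation; all are parameters
of `ClassifyParams`.  With several RING-H2 hits, each is evaluated and the
hit yielding the strongest label (CTL > ATL > BTL > CTL-like > unclassified)
wins, ties to the leftmost.  Every fired rule is recorded as an evidence
string in the call.

## Phylogenetic grouping

Because the eight ligands are obligate, domains align exactly without a
general-purpose aligner: ligand columns are fixed and each inter-ligand
spacer is right-padded with `-` to the widest spacer observed.  Distances are
pairwise-deletion p-distances (columns with a gap in either row are skipped
for that pair; a pair with no comparable columns is an error), optionally
Poisson-corrected (d = −ln(1 − p)).

Neighbor-Joining follows the standard Q-criterion.  Numerical choices: ties
in Q break to the smallest (i, j) pair in the current working order; negative
branch lengths are clamped to 0 with a warning; three remaining nodes are
closed with the exact star formulas; two taxa yield a single edge of length
d, serialized with the edge split at an anonymous midpoint (`(A:d/2,B:d/2);`)
so Newick stays binary.  On additive matrices the algorithm is exact, and the
test suite verifies recovery of topology and branch lengths to 1e−9 against
random generating trees and, for ≤ 6 taxa, against exhaustive topology
enumeration with least-squares branch fitting.

Bootstrap supports resample alignment columns with replacement (seeded
`numpy` generator); support of an internal edge is the fraction of replicate
trees containing its bipartition.  A degenerate replicate whose distance
computation fails contributes support to no split.

Group assignment walks leaf-to-leaf path lengths: each query leaf takes the
group of its nearest anchor; when the nearest anchors of two different groups
are nearly equidistant — relative margin (d2 − d1)/d2 below 0.1 — the leaf
lacks clear affinity and is assigned to the outlier group `H`.  The margin
rule is this package's own operationalization of what was originally a visual
judgement; the ratio is a parameter.

## Gene architecture

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted exactly once at I/O.  Gene models store exon/CDS/5′UTR
segments in transcript (5′→3′) orientation, so all counting is strand-aware
by construction.  The 5′UTR is always *derived* (exonic region strictly 5′ of
the first CDS base), which makes it exact and independent of whether the
annotation included UTR features.

* CDS introns = gaps between consecutive CDS segments (count =
  #CDS segments − 1).
* 5′UTR introns = gaps between consecutive 5′UTR segments, sizes in genomic
  nucleotides.
* An intron whose junction falls exactly at the UTR/CDS boundary (preceding
  exon all UTR, following exon starting with the CDS) is counted in neither
  column; this edge is a genuine ambiguity of the definitions and is resolved
  conservatively.

A splice junction lies "inside" a motif when the cumulative CDS length at the
junction falls strictly between 3·start and 3·end of the motif's protein
span (residue i ↔ CDS nucleotides [3i, 3i+3)).

## Synthetic data

The generator emulates exactly the statistical structure the classifier
assumes: a random flank (uniform residue composition by default,
configurable), for CTLs an instance of the YEELL consensus (constrained
positions drawn uniformly from their allowed sets, wildcards from the
background), a linker of 20–40 residues, and a RING-H2 domain drawn from the
label's profile with planted diagnostics for ATL/BTL.  Flanks are 60–100
residues.  Spacer residues inside the domain come from an alphabet without
Cys/His, so planted ligand positions are unambiguous.

Assemblies are rejection-sampled against the scanners themselves: a candidate
is re-drawn until the RING scan finds exactly the planted placement (or none,
for background), non-CTL labels contain no accidental YEELL window upstream of
the domain, and BTL domains do not accidentally satisfy two ATL diagnostics.
Controlled mutations are applied *after* this verification: either an exact
number of constrained motif positions (`motif_mutation_count`) or a
per-position rate, and a per-ligand mutation rate.  All randomness flows from
one seed through a single `numpy` generator, so outputs are bit-reproducible.

What the generator does **not** emulate: insertions/deletions, tree-structured
sequence evolution, realistic residue composition, multi-domain proteins, or
partial/truncated domains.  Perfect recovery on this synthetic world
demonstrates that the computation implements its definitions exactly; it does
not measure sensitivity on real proteomes, where domain boundaries and motif
degeneracy are messier.

Gene models are built from declarative exon/intron layouts (the last 5′UTR
exon shares a genomic exon with the first CDS segment); reading the written
GFF3 back and counting introns reproduces each layout exactly, including on
the minus strand, where models are mirrored coordinate-exactly.

## Problem sizes and verification

The shipped verification uses: 200 random sequences (≤ 200 aa) per scanner
for brute-force oracle agreement; 200 proteins (50 per label) at mutation
rate 0 and 500 CTLs with one planted motif mismatch for classifier
precision/recall; 100 random additive matrices (4–8 taxa) for NJ exactness;
100 bootstrap replicates for the clean-separation support check.  These sizes
make every property measurable in seconds while leaving the estimates
essentially deterministic.  `scripts/acceptance.py --seed S --out F` reruns
all of it from scratch and writes the measured numbers as JSON; no quantity
in this note or the README is asserted without being recomputed there or in
the test suite.

## Known limitations

* The grammar has no insertion tolerance beyond the profile ranges; a domain
  with an unusual gap outside every shipped profile is invisible unless the
  user supplies a wider profile.
* Diagnostic residues are hard offsets; compensatory shifts (e.g. the extra
  ATL residue between the conserved proline and ligand 3) are reported via
  the proline field but do not re-index the other diagnostics.
* ATL/BTL calls rest on RING diagnostics only — transmembrane-helix and BZF
  detection are out of scope, so an ATL lacking two of its three residues
  degrades to `RING-H2-unclassified` rather than being rescued by its
  N-terminus.
* NJ is the only tree method; no substitution-model distances beyond the
  Poisson correction, no rooting.
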