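"""Degenerate position-specific motif scanning and Chou–Fasman helix checks.

The central pattern is the 21-residue consensus surrounding the Y-E-E-L-L
core that marks CTL E3 ligases::

    (D/E/V)XX(S/T/N)(Y/F)E(E/Q/A)(L/M)(L/T/I)XLX(E/D/N)X(L/I/M)GX(V/A/E)XX(G/A/R)

Each position is either a set of allowed residues or a wildcard (``X``/``x``).
A window matches when the number of mismatches at constrained positions stays
within a budget (default 3 of the 14 constrained positions, i.e. ≈75%
identity).  Wildcard positions neither match nor mismatch; an ``X`` in the
*sequence* always counts as a mismatch at a constrained position.

The helix check implements the classic Chou–Fasman rules with the published
propensity table, since the motif is expected to sit on an α-helix.
"""

from __future__ import annotations

from dataclasses import dataclass

#: residue letters legal inside a consensus (wildcards handled separately)
_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: 21-residue consensus for the YEELL motif; core = the YEELL block
YEELL_CONSENSUS = ("(D/E/V)XX(S/T/N)(Y/F)E(E/Q/A)(L/M)(L/T/I)"
                   "XLX(E/D/N)X(L/I/M)GX(V/A/E)XX(G/A/R)")
YEELL_CORE = (4, 9)  # 0-based half-open within the pattern


class ConsensusParseError(ValueError):
    """Raised on a malformed consensus string; carries the column."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


@dataclass(frozen=True)
class MotifPattern:
    """Ordered positions, each an allowed-residue frozenset or None (wildcard)."""

    name: str
    positions: tuple[frozenset[str] | None, ...]
    core: tuple[int, int]
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"pattern {self.name}: length must be >= 1")
        s, e = self.core
        if not (0 <= s < e <= len(self.positions)):
            raise ValueError(f"pattern {self.name}: core {self.core} out of "
                             f"bounds for length {len(self.positions)}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_constrained(self) -> int:
        return sum(1 for p in self.positions if p is not None)


@dataclass(frozen=True)
class MotifHit:
    """A located match: 0-based half-open protein coordinates."""

    protein_id: str
    start: int
    end: int
    mismatches: int
    score: float


def parse_consensus(text: str, name: str = "motif",
                    core: tuple[int, int] | None = None,
                    max_mismatch: int = 3) -> MotifPattern:
    """Parse a ``(A/B/…)`` / single-letter / ``X`` consensus into a pattern.

    ``core`` is a 0-based half-open sub-range; when omitted it defaults to the
    whole pattern.
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "(":
            j = text.find(")", i)
            if j < 0:
                raise ConsensusParseError("unbalanced parenthesis", i + 1)
            tokens = text[i + 1:j].split("/")
            group = set()
            for tok in tokens:
                tok = tok.strip().upper()
                if len(tok) != 1 or tok not in _RESIDUES:
                    raise ConsensusParseError(
                        f"illegal residue {tok!r} in group", i + 1)
                group.add(tok)
            positions.append(frozenset(group))
            i = j + 1
        elif c in "Xx":
            positions.append(None)
            i += 1
        elif c.upper() in _RESIDUES:
            positions.append(frozenset(c.upper()))
            i += 1
        elif c.isspace():
            i += 1
        else:
            raise ConsensusParseError(f"illegal character {c!r}", i + 1)
    if not positions:
        raise ConsensusParseError("empty consensus", 1)
    return MotifPattern(name=name, positions=tuple(positions),
                        core=core if core is not None else (0, len(positions)),
                        max_mismatch=max_mismatch)


def yeell_pattern(max_mismatch: int = 3) -> MotifPattern:
    """The shipped YEELL pattern: 21 positions, 14 constrained, 5-residue core."""
    return parse_consensus(YEELL_CONSENSUS, name="YEELL", core=YEELL_CORE,
                           max_mismatch=max_mismatch)


def builtin_patterns() -> dict[str, MotifPattern | None]:
    """Named patterns shipped with the package.

    GLD (ATL) and GLD-like (BTL) are placeholders: their residue composition
    was published only as sequence-LOGO figures, so users must supply their own
    consensus strings to scan for them.
    """
    return {"YEELL": yeell_pattern(), "GLD": None, "GLD-like": None}


def scan_motif(record, pattern: MotifPattern,
               max_mismatch: int | None = None) -> list[MotifHit]:
    """All windows matching ``pattern`` within the mismatch budget, in order.

    Overlapping hits are all reported; filtering is the classifier's concern.
    ``record`` needs ``.id`` and ``.seq`` (a bare string is accepted).
    """
    if pattern is None:
        raise ValueError("pattern is a placeholder with no consensus; "
                         "supply a consensus string to scan for it")
    if isinstance(record, str):
        pid, seq = "", record
    else:
        pid, seq = record.id, record.seq
    budget = pattern.max_mismatch if max_mismatch is None else max_mismatch
    if budget < 0:
        raise ValueError("max_mismatch must be >= 0")
    L = len(pattern)
    constrained = pattern.n_constrained
    hits: list[MotifHit] = []
    for start in range(len(seq) - L + 1):
        mism = 0
        for k, allowed in enumerate(pattern.positions):
            if allowed is None:
                continue
            if seq[start + k] not in allowed:  # X never satisfies a class
                mism += 1
                if mism > budget:
                    break
        else:
            hits.append(MotifHit(
                protein_id=pid, start=start, end=start + L, mismatches=mism,
                score=(constrained - mism) / constrained))
    return hits


# ---------------------------------------------------------------------------
# Chou–Fasman α-helix prediction
# ---------------------------------------------------------------------------

#: published Chou–Fasman helix propensities Pα
P_ALPHA = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
    "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
    "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
    "W": 1.08, "Y": 0.69,
}

#: published Chou–Fasman sheet propensities Pβ
P_BETA = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
    "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30, "M": 1.05, "N": 0.89,
    "P": 0.55, "Q": 1.10, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.70,
    "W": 1.37, "Y": 1.47,
}

NUCLEATION_WINDOW = 6
NUCLEATION_FORMERS = 4
NUCLEATION_THRESHOLD = 1.03
EXTENSION_WINDOW = 4
EXTENSION_CUTOFF = 1.00


def _pa(aa: str) -> float:
    return P_ALPHA.get(aa, 0.0)  # X: never helix-forming


def _pb(aa: str) -> float:
    return P_BETA.get(aa, 0.0)


def chou_fasman_helix(seq: str) -> list[tuple[int, int]]:
    """Classic Chou–Fasman helix segments as 0-based half-open intervals.

    A 6-residue window with ≥4 residues of Pα > 1.03 nucleates; the segment
    extends in both directions while the trailing 4-residue mean Pα stays
    ≥ 1.00; overlapping segments merge, and a merged segment is reported only
    where its mean Pα exceeds its mean Pβ.
    """
    n = len(seq)
    if n < NUCLEATION_WINDOW:
        return []
    pa = [_pa(c) for c in seq]

    raw: list[tuple[int, int]] = []
    for i in range(n - NUCLEATION_WINDOW + 1):
        window = pa[i:i + NUCLEATION_WINDOW]
        if sum(1 for p in window if p > NUCLEATION_THRESHOLD) < NUCLEATION_FORMERS:
            continue
        start, end = i, i + NUCLEATION_WINDOW
        while end < n:
            tail = pa[end - EXTENSION_WINDOW + 1:end + 1]
            if sum(tail) / EXTENSION_WINDOW < EXTENSION_CUTOFF:
                break
            end += 1
        while start > 0:
            head = pa[start - 1:start - 1 + EXTENSION_WINDOW]
            if sum(head) / EXTENSION_WINDOW < EXTENSION_CUTOFF:
                break
            start -= 1
        raw.append((start, end))

    merged: list[tuple[int, int]] = []
    for s, e in sorted(raw):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))

    out = []
    for s, e in merged:
        mean_a = sum(pa[s:e]) / (e - s)
        mean_b = sum(_pb(c) for c in seq[s:e]) / (e - s)
        if mean_a > mean_b:
            out.append((s, e))
    return out


def motif_helix_check(record, hit: MotifHit,
                      min_overlap_frac: float = 0.5) -> bool:
    """True when a predicted helix covers at least half of the motif window."""
    seq = record if isinstance(record, str) else record.seq
    need = min_overlap_frac * (hit.end - hit.start)
    for s, e in chou_fasman_helix(seq):
        overlap = min(e, hit.end) - max(s, hit.start)
        if overlap >= need:
            return True
    return False
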