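"""Sequence-level analysis of SOX binding probes and the dimerization region.

Covers degenerate-motif scanning of double-stranded probes, palindrome and
site-spacing checks, helical-wheel projection of a putative amphipathic helix,
hydrophobic-face detection, and a rule-based dimerization-phenotype call for
single-residue substitution mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic alphabet for face detection.  Gly, Pro and Cys are
#: treated as non-hydrophobic: on a helical wheel they do not contribute to a
#: dimerization interface the way the aliphatic/aromatic side chains do.
HYDROPHOBIC_DEFAULT: FrozenSet[str] = frozenset("AVILMFWY")

IUPAC: Dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T (or IUPAC-degenerate) string."""
    table = _IUPAC_COMPLEMENT
    try:
        return "".join(table[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide code {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteHit:
    """A motif occurrence, in top-strand coordinates (0-based, half-open)."""

    start: int
    length: int
    strand: str  # '+' or '-'
    matched: str  # literal top-strand footprint [start, start+length)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class DuplexProbe:
    """A double-stranded DNA probe.

    Only the top strand is stored; the bottom strand is always its reverse
    complement.
    """

    name: str
    top_strand: str
    site_hits: List[SiteHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.top_strand = self.top_strand.upper()
        if not self.top_strand:
            raise ValueError("probe top strand must be non-empty")
        bad = set(self.top_strand) - set("ACGT")
        if bad:
            raise ValueError(f"probe {self.name!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.top_strand)

    @property
    def bottom_strand(self) -> str:
        return reverse_complement(self.top_strand)


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC-degenerate motif with a per-position mismatch budget (no indels)."""

    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise ValueError("motif pattern must be non-empty")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {pat!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")

    def __len__(self) -> int:
        return len(self.pattern)

    def mismatches(self, window: str) -> int:
        """Per-position mismatch count of ``window`` against the pattern."""
        return sum(1 for base, code in zip(window, self.pattern) if base not in IUPAC[code])


@dataclass(frozen=True)
class ProteinRegion:
    """A protein segment with explicit residue numbering (1-based convention).

    Residue i of the region (0-based index into ``sequence``) is numbered
    ``start + i``.
    """

    sequence: str
    start: int
    label: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid amino-acid code(s) {sorted(bad)}")
        if self.start < 1:
            raise ValueError("start residue number must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residue_numbers(self) -> range:
        return range(self.start, self.start + len(self.sequence))

    def residue(self, number: int) -> str:
        if number not in self.residue_numbers:
            raise KeyError(f"residue {number} outside region {self.start}..{self.start + len(self) - 1}")
        return self.sequence[number - self.start]


@dataclass
class WheelProjection:
    """Helical-wheel geometry: residue number -> azimuthal angle in degrees.

    The canonical alpha-helix advances 100 degrees per residue; the first
    residue of the region sits at 0 degrees.
    """

    degrees_per_residue: float = 100.0
    hydrophobic_set: FrozenSet[str] = HYDROPHOBIC_DEFAULT

    def angles(self, region: ProteinRegion) -> Dict[int, float]:
        return {
            r: (i * self.degrees_per_residue) % 360.0
            for i, r in enumerate(region.residue_numbers)
        }


@dataclass(frozen=True)
class FaceReport:
    """Outcome of hydrophobic-face detection on a helical wheel."""

    residues: Tuple[int, ...]  # residue numbers on the hydrophobic face
    arc_start: Optional[float]  # degrees; None if face is empty
    arc_span: Optional[float]  # degrees; None if face is empty or full wheel
    clean_separation: bool  # smallest arc excludes all non-hydrophobic residues


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def scan_motif(probe: DuplexProbe, motif: MotifPattern) -> List[SiteHit]:
    """All motif occurrences on both strands of a duplex probe.

    A minus-strand hit is a window whose reverse complement matches the
    pattern; its footprint is still reported in top-strand coordinates.
    Hits are sorted by start, then '+' before '-'.  A motif longer than the
    probe yields an empty list.
    """
    seq = probe.top_strand
    L = len(motif)
    rc_pattern = MotifPattern(reverse_complement(motif.pattern), motif.max_mismatch)
    hits: List[SiteHit] = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if motif.mismatches(window) <= motif.max_mismatch:
            hits.append(SiteHit(start, L, "+", window))
        # matching the reverse-complement pattern on the top strand is
        # equivalent to matching the pattern on the bottom strand
        if rc_pattern.mismatches(window) <= motif.max_mismatch:
            hits.append(SiteHit(start, L, "-", window))
    hits.sort(key=lambda h: (h.start, h.strand != "+"))
    return hits


def check_palindrome(probe: DuplexProbe) -> bool:
    """True iff the top strand equals its own reverse complement."""
    return probe.top_strand == probe.bottom_strand


def site_spacing(hits: Sequence[SiteHit]) -> int:
    """Base pairs strictly between two opposite-strand site footprints."""
    if len(hits) != 2:
        raise ValueError(f"site_spacing needs exactly 2 hits, got {len(hits)}")
    a, b = hits
    if a.strand == b.strand:
        raise ValueError("site_spacing needs hits on opposite strands")
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = right.start - left.end
    if gap < 0:
        raise ValueError("site footprints overlap; spacing undefined")
    return gap


def _smallest_enclosing_arc(angles: Sequence[float]) -> Tuple[float, float]:
    """Smallest circular arc [start, start+span] covering all angles.

    Ties are broken by the smallest arc start angle.  Returns (start, span)
    in degrees.
    """
    pts = sorted({a % 360.0 for a in angles})
    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    # the smallest covering arc is the complement of the largest gap
    best_gap, best_start = -1.0, pts[0]
    for i in range(n):
        nxt = pts[(i + 1) % n]
        gap = (nxt - pts[i]) % 360.0
        if gap > best_gap or (gap == best_gap and nxt < best_start):
            best_gap, best_start = gap, nxt
    return best_start, 360.0 - best_gap


def _on_arc(angle: float, start: float, span: float) -> bool:
    return (angle - start) % 360.0 <= span + 1e-9


def hydrophobic_face(
    region: ProteinRegion, wheel: Optional[WheelProjection] = None
) -> FaceReport:
    """Detect the hydrophobic face of a candidate amphipathic helix.

    Projects the region on a helical wheel, collects the hydrophobic residues,
    finds the smallest wheel arc covering them, and reports whether that arc
    excludes every non-hydrophobic residue (a "clean" amphipathic separation).
    """
    if len(region) < 4:
        raise ValueError("region too short for wheel analysis (need >= 4 residues)")
    wheel = wheel or WheelProjection()
    angles = wheel.angles(region)
    hydro = [r for r in region.residue_numbers if region.residue(r) in wheel.hydrophobic_set]
    polar = [r for r in region.residue_numbers if r not in hydro]
    if not hydro:
        return FaceReport((), None, None, False)
    start, span = _smallest_enclosing_arc([angles[r] for r in hydro])
    if not polar:
        # every residue hydrophobic: no amphipathic separation to speak of
        return FaceReport(tuple(hydro), start, span, False)
    clean = not any(_on_arc(angles[r], start, span) for r in polar)
    return FaceReport(tuple(hydro), start, span, clean)


#: Residues whose substitution abolished dimerization: the hydrophobic face of
#: the dimerization helix plus the two-residue HMG-domain platform.
FACE_RESIDUES_DEFAULT: FrozenSet[int] = frozenset({73, 76, 77, 80, 81, 84})
PLATFORM_RESIDUES_DEFAULT: FrozenSet[int] = frozenset({119, 142})
#: Positions assayed (here or in prior work) with no effect on dimerization.
NEUTRAL_RESIDUES_DEFAULT: FrozenSet[int] = frozenset({78, 79, 118, 145})


def predict_phenotype(
    position: int,
    new_aa: str = "",
    face_residues: FrozenSet[int] = FACE_RESIDUES_DEFAULT,
    platform_residues: FrozenSet[int] = PLATFORM_RESIDUES_DEFAULT,
    neutral_residues: FrozenSet[int] = NEUTRAL_RESIDUES_DEFAULT,
) -> str:
    """Rule-based dimerization call for a single-residue substitution.

    Returns ``'loss'`` if the position belongs to the hydrophobic face or the
    HMG platform, ``'retained'`` if it is an assayed neutral position, and
    ``'unknown'`` otherwise.  ``new_aa`` is accepted for notation (e.g. V77E)
    but the call is positional: every assayed substitution at a face/platform
    position lost dimerization regardless of the replacement.
    """
    if position in face_residues or position in platform_residues:
        return "loss"
    if position in neutral_residues:
        return "retained"
    return "unknown"
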