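"""Typed geometric restraints with flat-bottom harmonic energies.

All restraints share one energy form: zero inside a tolerance band around the
target and ``k * (excess)^2`` outside it.  Ambiguous interaction restraints
(AIRs) act on an r^-6-summed effective distance over a set of candidate bead
pairs, so any one close pair can satisfy the restraint; AIRs and hydrogen-bond
restraints penalize only upper-bound violations.

The synthesis routines build the restraints the assembly pipeline consumes:
alpha-helix maintenance restraints for the dimerization helix, mutagenesis
AIRs between the helix face and the HMG-domain platform, and distance
restraints sampled from a docked pose.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist

from .core import BeadId, BeadSystem
from .geometry import dihedral
from .seqtools import ProteinRegion

__all__ = [
    "DistanceRestraint",
    "HBondRestraint",
    "AmbiguousRestraint",
    "TorsionRestraint",
    "PlanarityRestraint",
    "RestraintSet",
    "Violation",
    "effective_distance",
    "helix_restraints",
    "make_airs",
    "sample_contact_restraints",
    "AIR_SURFACE_TARGET",
    "AIR_BEAD_OFFSET",
]

#: AIR target between residue surfaces (Angstrom), per the short-distance
#: ambiguous-restraint convention.
AIR_SURFACE_TARGET = 2.0
#: Calibration offset mapping the surface target onto C-alpha bead distances:
#: coarse beads sit at side-chain centres-of-mass scale and cannot approach to
#: 2 A, so the bead-level AIR target is surface target + offset.
AIR_BEAD_OFFSET = 3.0

#: Helix maintenance defaults: C-alpha pseudo-torsion and i->i+3 / i->i+4
#: distances of a canonical alpha-helix.
HELIX_TORSION_TARGET = 50.0  # degrees
HELIX_TORSION_HALF_WIDTH = 10.0  # degrees
HELIX_I3_TARGET = 5.1  # Angstrom
HELIX_I4_TARGET = 6.2  # Angstrom
HELIX_DISTANCE_PAD = 0.3  # Angstrom


# ---------------------------------------------------------------------------
# restraint records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceRestraint:
    """Two-sided flat-bottom distance restraint between two beads."""

    bead_a: BeadId
    bead_b: BeadId
    target: float
    lower_pad: float = 0.5
    upper_pad: float = 0.5
    force_k: float = 1.0

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("distance target must be positive")
        if self.lower_pad < 0 or self.upper_pad < 0:
            raise ValueError("pads must be non-negative")

    upper_only: bool = False

    def deviation(self, system: BeadSystem) -> float:
        d = float(np.linalg.norm(system.resolve(self.bead_a) - system.resolve(self.bead_b)))
        return d - self.target

    def energy(self, system: BeadSystem) -> Tuple[float, float]:
        """(energy, violation beyond the flat bottom) for the current coords."""
        dev = self.deviation(system)
        if dev > self.upper_pad:
            excess = dev - self.upper_pad
        elif dev < -self.lower_pad and not self.upper_only:
            excess = -dev - self.lower_pad
        else:
            excess = 0.0
        return self.force_k * excess * excess, excess

    def beads(self) -> Tuple[BeadId, ...]:
        return (self.bead_a, self.bead_b)


@dataclass(frozen=True)
class HBondRestraint(DistanceRestraint):
    """Hydrogen-bond-like i->i+3 / i->i+4 distance restraint (upper bound only)."""

    upper_only: bool = True


@dataclass(frozen=True)
class AmbiguousRestraint:
    """Ambiguous interaction restraint between two bead groups.

    Satisfied when the r^-6-summed effective distance over all cross-group
    pairs falls at or below the target; only upper violations are penalized.
    """

    group_a: Tuple[BeadId, ...]
    group_b: Tuple[BeadId, ...]
    target: float = AIR_SURFACE_TARGET + AIR_BEAD_OFFSET
    force_k: float = 1.0

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("AIR groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("AIR groups must be disjoint")

    def energy(self, system: BeadSystem) -> Tuple[float, float]:
        d_eff = effective_distance(self, system)
        excess = max(0.0, d_eff - self.target)
        return self.force_k * excess * excess, excess

    def beads(self) -> Tuple[BeadId, ...]:
        return self.group_a + self.group_b


@dataclass(frozen=True)
class TorsionRestraint:
    """Flat-bottom restraint on the dihedral of four consecutive beads."""

    beads_abcd: Tuple[BeadId, BeadId, BeadId, BeadId]
    target: float  # degrees
    half_width: float = HELIX_TORSION_HALF_WIDTH  # degrees
    force_k: float = 1.0

    def __post_init__(self) -> None:
        chains = {b.chain for b in self.beads_abcd}
        if len(chains) != 1:
            raise ValueError("torsion beads must lie on one chain")
        resids = [b.resid for b in self.beads_abcd]
        if resids != list(range(resids[0], resids[0] + 4)):
            raise ValueError("torsion beads must be consecutive residues")

    def energy(self, system: BeadSystem) -> Tuple[float, float]:
        pts = [system.resolve(b) for b in self.beads_abcd]
        obs = dihedral(*pts)
        dev = (obs - self.target + 180.0) % 360.0 - 180.0
        excess = max(0.0, abs(dev) - self.half_width)
        return self.force_k * excess * excess, excess

    def beads(self) -> Tuple[BeadId, ...]:
        return self.beads_abcd


@dataclass(frozen=True)
class PlanarityRestraint:
    """Flat-bottom restraint on the RMS deviation of beads from their best plane."""

    bead_group: Tuple[BeadId, ...]
    max_rms_deviation: float = 0.5  # Angstrom
    force_k: float = 1.0

    def __post_init__(self) -> None:
        if len(self.bead_group) < 4:
            raise ValueError("planarity restraint needs at least 4 beads")

    def energy(self, system: BeadSystem) -> Tuple[float, float]:
        pts = np.array([system.resolve(b) for b in self.bead_group])
        centred = pts - pts.mean(axis=0)
        # smallest singular value direction = plane normal; residuals along it
        _, s, _ = np.linalg.svd(centred, full_matrices=False)
        rms = float(s[-1] / np.sqrt(len(pts)))
        excess = max(0.0, rms - self.max_rms_deviation)
        return self.force_k * excess * excess, excess

    def beads(self) -> Tuple[BeadId, ...]:
        return self.bead_group


Restraint = Union[
    DistanceRestraint, HBondRestraint, AmbiguousRestraint, TorsionRestraint,
    PlanarityRestraint,
]


@dataclass(frozen=True)
class Violation:
    restraint: Restraint
    excess: float  # deviation beyond the flat bottom
    energy: float


@dataclass
class RestraintSet:
    """Typed collection of restraints with a provenance (stage) tag."""

    distances: List[DistanceRestraint] = field(default_factory=list)
    ambiguous: List[AmbiguousRestraint] = field(default_factory=list)
    torsions: List[TorsionRestraint] = field(default_factory=list)
    planarities: List[PlanarityRestraint] = field(default_factory=list)
    stage: str = ""

    def __len__(self) -> int:
        return (
            len(self.distances) + len(self.ambiguous) + len(self.torsions)
            + len(self.planarities)
        )

    def __iter__(self):
        yield from self.distances
        yield from self.ambiguous
        yield from self.torsions
        yield from self.planarities

    def extend(self, other: "RestraintSet") -> "RestraintSet":
        self.distances.extend(other.distances)
        self.ambiguous.extend(other.ambiguous)
        self.torsions.extend(other.torsions)
        self.planarities.extend(other.planarities)
        return self

    def add(self, restraint: Restraint) -> None:
        if isinstance(restraint, AmbiguousRestraint):
            self.ambiguous.append(restraint)
        elif isinstance(restraint, DistanceRestraint):
            self.distances.append(restraint)
        elif isinstance(restraint, TorsionRestraint):
            self.torsions.append(restraint)
        elif isinstance(restraint, PlanarityRestraint):
            self.planarities.append(restraint)
        else:
            raise TypeError(f"unknown restraint type {type(restraint)!r}")

    # -- evaluation --------------------------------------------------------
    def evaluate(self, system: BeadSystem) -> Tuple[float, List[Violation]]:
        """Total flat-bottom energy plus violations sorted by energy, descending."""
        total = 0.0
        violations: List[Violation] = []
        for r in self:
            for bead in r.beads():
                if bead.chain not in system.chains:
                    raise KeyError(f"restraint references unresolvable bead {bead}")
            e, excess = r.energy(system)
            total += e
            if excess > 0:
                violations.append(Violation(r, excess, e))
        violations.sort(key=lambda v: -v.energy)
        return total, violations

    def satisfied_fraction(self, system: BeadSystem) -> float:
        if len(self) == 0:
            return 1.0
        _, violations = self.evaluate(system)
        return 1.0 - len(violations) / len(self)

    # -- serialization -----------------------------------------------------
    def to_tsv(self) -> str:
        """Serialize to a one-row-per-restraint TSV dialect (lossless)."""
        rows = ["type\tselection_a\tselection_b\ttarget\tlower_pad\tupper_pad\tforce_k\tstage"]

        def sel(beads: Sequence[BeadId]) -> str:
            return ",".join(str(b) for b in beads)

        for r in self.distances:
            kind = "hbond" if isinstance(r, HBondRestraint) else "distance"
            rows.append(
                f"{kind}\t{r.bead_a}\t{r.bead_b}\t{r.target!r}\t{r.lower_pad!r}"
                f"\t{r.upper_pad!r}\t{r.force_k!r}\t{self.stage}"
            )
        for r in self.ambiguous:
            rows.append(
                f"air\t{sel(r.group_a)}\t{sel(r.group_b)}\t{r.target!r}\t0.0\t0.0"
                f"\t{r.force_k!r}\t{self.stage}"
            )
        for r in self.torsions:
            rows.append(
                f"torsion\t{sel(r.beads_abcd)}\t\t{r.target!r}\t{r.half_width!r}"
                f"\t{r.half_width!r}\t{r.force_k!r}\t{self.stage}"
            )
        for r in self.planarities:
            rows.append(
                f"planarity\t{sel(r.bead_group)}\t\t{r.max_rms_deviation!r}\t0.0\t0.0"
                f"\t{r.force_k!r}\t{self.stage}"
            )
        return "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "RestraintSet":
        rset = cls()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            return rset
        header = lines[0].split("\t")
        if header[0] != "type":
            raise ValueError("restraint TSV must start with its header row")
        for lineno, line in enumerate(lines[1:], start=2):
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(f"restraint TSV line {lineno}: expected 8 columns")
            kind, sel_a, sel_b, target, lo, hi, k, stage = parts
            rset.stage = stage
            beads_a = tuple(BeadId.parse(t) for t in sel_a.split(",") if t)
            beads_b = tuple(BeadId.parse(t) for t in sel_b.split(",") if t)
            if kind in ("distance", "hbond"):
                klass = HBondRestraint if kind == "hbond" else DistanceRestraint
                rset.add(klass(beads_a[0], beads_b[0], float(target), float(lo), float(hi), float(k)))
            elif kind == "air":
                rset.add(AmbiguousRestraint(beads_a, beads_b, float(target), float(k)))
            elif kind == "torsion":
                rset.add(TorsionRestraint(beads_a, float(target), float(lo), float(k)))
            elif kind == "planarity":
                rset.add(PlanarityRestraint(beads_a, float(target), float(k)))
            else:
                raise ValueError(f"restraint TSV line {lineno}: unknown type {kind!r}")
        return rset


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def effective_distance(air: AmbiguousRestraint, system: BeadSystem) -> float:
    """r^-6-summed effective distance of an AIR: (sum d_ij^-6)^(-1/6).

    Always at or below the minimum pairwise distance.  Defined as 0 when any
    cross pair is coincident.
    """
    pa = np.array([system.resolve(b) for b in air.group_a])
    pb = np.array([system.resolve(b) for b in air.group_b])
    d = cdist(pa, pb)
    if np.any(d == 0.0):
        return 0.0
    return float((d**-6).sum() ** (-1.0 / 6.0))


def helix_restraints(
    region: ProteinRegion,
    chain_id: str,
    *,
    torsion_target: float = HELIX_TORSION_TARGET,
    torsion_half_width: float = HELIX_TORSION_HALF_WIDTH,
    force_k: float = 1.0,
    stage: str = "helix",
) -> RestraintSet:
    """Alpha-helix maintenance restraints over a protein region.

    Emits a C-alpha pseudo-torsion restraint for every 4-residue window and
    hydrogen-bond-like i->i+3 / i->i+4 upper-bound distance restraints, the
    standard coarse encoding of canonical helical geometry.
    """
    if len(region) < 5:
        raise ValueError("helix restraints need a region of at least 5 residues")
    first, last = region.start, region.start + len(region) - 1
    rset = RestraintSet(stage=stage)
    for r in range(first, last - 2):
        rset.add(
            TorsionRestraint(
                tuple(BeadId(chain_id, r + j) for j in range(4)),
                target=torsion_target,
                half_width=torsion_half_width,
                force_k=force_k,
            )
        )
    for r in range(first, last - 2):
        rset.add(
            HBondRestraint(
                BeadId(chain_id, r), BeadId(chain_id, r + 3),
                target=HELIX_I3_TARGET, lower_pad=HELIX_DISTANCE_PAD,
                upper_pad=HELIX_DISTANCE_PAD, force_k=force_k,
            )
        )
    for r in range(first, last - 3):
        rset.add(
            HBondRestraint(
                BeadId(chain_id, r), BeadId(chain_id, r + 4),
                target=HELIX_I4_TARGET, lower_pad=HELIX_DISTANCE_PAD,
                upper_pad=HELIX_DISTANCE_PAD, force_k=force_k,
            )
        )
    return rset


def make_airs(
    active_a: Sequence[int],
    active_b: Sequence[int],
    passive_b: Sequence[int] = (),
    *,
    chain_a: str = "A",
    chain_b: str = "B",
    target: float = AIR_SURFACE_TARGET + AIR_BEAD_OFFSET,
    force_k: float = 1.0,
    stage: str = "airs",
) -> RestraintSet:
    """Mutagenesis-derived AIRs: one per active residue on the mobile side.

    Each active residue of chain ``chain_a`` receives one ambiguous restraint
    against all active plus passive residues of ``chain_b`` — the restraint is
    satisfied as soon as the residue approaches any member of that surface.
    """
    if not active_a:
        raise ValueError("active_a must be non-empty")
    if not active_b:
        raise ValueError("active_b must be non-empty")
    group_b_res = list(dict.fromkeys(list(active_b) + list(passive_b)))
    if chain_a == chain_b and set(active_a) & set(group_b_res):
        raise ValueError("active_a overlaps the partner residue set on the same chain")
    rset = RestraintSet(stage=stage)
    group_b = tuple(BeadId(chain_b, r) for r in group_b_res)
    for res in active_a:
        rset.add(
            AmbiguousRestraint(
                group_a=(BeadId(chain_a, res),),
                group_b=group_b,
                target=target,
                force_k=force_k,
            )
        )
    return rset


def sample_contact_restraints(
    system: BeadSystem,
    chain_a: str,
    chain_b: str,
    n: int = 50,
    cutoff: float = 8.0,
    seed: Optional[int] = None,
    *,
    residues_a: Optional[Iterable[int]] = None,
    residues_b: Optional[Iterable[int]] = None,
    pad: float = 0.5,
    stage: str = "contacts",
) -> RestraintSet:
    """Sample ``n`` cross-chain contact restraints from the current pose.

    Eligible pairs are all (chain_a, chain_b) bead pairs within ``cutoff``;
    ``n`` of them are drawn uniformly without replacement and each restraint's
    target is set to the current distance, so the emitted set scores zero on
    the source pose.  The eligible list is sorted lexicographically before
    shuffling so a seed reproduces the same sample on any platform.
    """
    ca = system.chains[chain_a]
    cb = system.chains[chain_b]
    mask_a = np.ones(len(ca), dtype=bool)
    mask_b = np.ones(len(cb), dtype=bool)
    if residues_a is not None:
        wanted = set(residues_a)
        mask_a = np.array([r in wanted for r in ca.residue_numbers])
    if residues_b is not None:
        wanted = set(residues_b)
        mask_b = np.array([r in wanted for r in cb.residue_numbers])
    res_a = ca.residue_numbers[mask_a]
    res_b = cb.residue_numbers[mask_b]
    d = cdist(ca.coords[mask_a], cb.coords[mask_b])
    ii, jj = np.where(d <= cutoff)
    eligible = sorted(
        (int(res_a[i]), int(res_b[j]), float(d[i, j])) for i, j in zip(ii, jj)
    )
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} cross-chain pairs within {cutoff} A; need {n}"
        )
    rng = random.Random(seed)
    order = list(range(len(eligible)))
    rng.shuffle(order)
    rset = RestraintSet(stage=stage)
    for idx in sorted(order[:n]):
        ra, rb, dist = eligible[idx]
        rset.add(
            DistanceRestraint(
                BeadId(chain_a, ra), BeadId(chain_b, rb),
                target=dist, lower_pad=pad, upper_pad=pad,
            )
        )
    return rset
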