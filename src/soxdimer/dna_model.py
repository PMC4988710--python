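"""Coarse-grained B-DNA built from base-pair step parameters.

Each base pair carries a frame (origin + orthonormal triad: x into the major
groove, z along the local helix axis).  Frames are propagated step by step by
composing twist/roll/tilt rotations with a rise translation; beads (one per
strand nucleotide, at approximate phosphate positions) are reconstructed from
the frames.  Site-directed bends are imposed as roll increments distributed
across a binding-site footprint, and the overall axis bend is measured between
terminal windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import BeadId, BeadSystem, ChainModel
from .geometry import angle_between, rotation_about_axis
from .restraints import DistanceRestraint, PlanarityRestraint, RestraintSet
from .seqtools import reverse_complement

__all__ = [
    "StepParams",
    "BasePairFrame",
    "BendSpec",
    "DNAModel",
    "build_bdna",
    "apply_site_bend",
    "measure_bend",
    "derive_dna_restraints",
]

#: Lateral offset of the two strand beads from the base-pair origin along the
#: frame y axis (approximate phosphate radius at coarse resolution).
BEAD_OFFSET = 4.5  # Angstrom

TOP_CHAIN = "C"
BOTTOM_CHAIN = "D"


@dataclass(frozen=True)
class StepParams:
    """Helicoidal base-pair step parameters (canonical B-DNA defaults)."""

    twist: float = 36.0  # degrees about the local z axis
    rise: float = 3.4  # Angstrom along the local z axis
    roll: float = 0.0  # degrees about the local y axis (bends the helix axis)
    tilt: float = 0.0  # degrees about the local x axis

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        for name in ("roll", "tilt"):
            v = getattr(self, name)
            if not -90.0 < v < 90.0:
                raise ValueError(f"{name} must lie in (-90, 90) degrees")


@dataclass
class BasePairFrame:
    """Origin and orthonormal triad of one base pair.

    Triad columns are the frame axes: x into the major groove, y along the
    long base-pair axis, z along the local helix axis.
    """

    origin: np.ndarray
    triad: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.triad = np.asarray(self.triad, dtype=float)
        if not np.allclose(self.triad @ self.triad.T, np.eye(3), atol=1e-9):
            raise ValueError("frame triad must be orthonormal")

    @property
    def x(self) -> np.ndarray:
        return self.triad[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.triad[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.triad[:, 2]

    def copy(self) -> "BasePairFrame":
        return BasePairFrame(self.origin.copy(), self.triad.copy())


@dataclass(frozen=True)
class BendSpec:
    """Per-site bends imposed as roll increments over site footprints.

    ``site_footprints`` are [start, end) base-pair intervals; each receives
    ``per_site_bend`` degrees of bend, distributed uniformly across the steps
    inside its footprint.  With ``coplanar=True`` (default) the bend axes of
    all sites are phased into one common plane anchored at the first site's
    major-groove direction, so multi-site bends compose additively; with
    ``coplanar=False`` each site bends toward the major groove at its own
    centre, and the composed bend depends on the helical phase between sites.
    """

    site_footprints: Tuple[Tuple[int, int], ...]
    per_site_bend: float  # degrees per site
    coplanar: bool = True

    def __post_init__(self) -> None:
        ivals = sorted(self.site_footprints)
        for (s, e) in ivals:
            if e - s < 2:
                raise ValueError("site footprints must span at least 2 bp")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("site footprints must not overlap")


@dataclass
class DNAModel:
    """Duplex DNA: top-strand sequence, per-bp frames, per-step parameters."""

    sequence: str
    frames: List[BasePairFrame]
    steps: List[StepParams]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.sequence):
            raise ValueError("need one frame per base pair")
        if len(self.steps) != max(len(self.sequence) - 1, 0):
            raise ValueError("need one step parameter set per base-pair step")

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "DNAModel":
        return DNAModel(self.sequence, [f.copy() for f in self.frames], list(self.steps))

    # -- bead view ----------------------------------------------------------
    def bead_coords(self) -> Tuple[np.ndarray, np.ndarray]:
        """(top-strand beads, bottom-strand beads), each shape (n, 3).

        Beads sit at +/- BEAD_OFFSET along each frame's y axis; they are a
        pure function of the frames.
        """
        top = np.array([f.origin + BEAD_OFFSET * f.y for f in self.frames])
        bottom = np.array([f.origin - BEAD_OFFSET * f.y for f in self.frames])
        return top, bottom

    def to_chains(self) -> Tuple[ChainModel, ChainModel]:
        """Bead chains: top strand as chain C, bottom strand as chain D.

        Both chains are numbered 1..n by base-pair index, so C:i pairs D:i.
        """
        top, bottom = self.bead_coords()
        n = len(self)
        nums = np.arange(1, n + 1)
        return (
            ChainModel(TOP_CHAIN, nums, top),
            ChainModel(BOTTOM_CHAIN, nums.copy(), bottom),
        )

    def to_system(self) -> BeadSystem:
        return BeadSystem.from_chains(self.to_chains())


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _step_rotation(step: StepParams, extra_roll: float = 0.0, phase: float = 0.0) -> np.ndarray:
    """Local rotation carrying frame i onto frame i+1.

    ``extra_roll`` is a bend increment applied about the local y axis rotated
    by ``phase`` degrees about z (phase 0 bends toward the major groove).
    """
    r = rotation_about_axis([0, 0, 1], step.twist)
    r = r @ rotation_about_axis([0, 1, 0], step.roll)
    r = r @ rotation_about_axis([1, 0, 0], step.tilt)
    if extra_roll != 0.0:
        axis = rotation_about_axis([0, 0, 1], phase) @ np.array([0.0, 1.0, 0.0])
        r = rotation_about_axis(axis, extra_roll) @ r
    return r


def _propagate(
    sequence: str,
    steps: Sequence[StepParams],
    bend_roll: Optional[Sequence[float]] = None,
    bend_phase: Optional[Sequence[float]] = None,
) -> List[BasePairFrame]:
    n = len(sequence)
    frames = [BasePairFrame(np.zeros(3), np.eye(3))]
    for i in range(n - 1):
        prev = frames[-1]
        extra = bend_roll[i] if bend_roll is not None else 0.0
        phase = bend_phase[i] if bend_phase is not None else 0.0
        local = _step_rotation(steps[i], extra, phase)
        triad = prev.triad @ local
        origin = prev.origin + prev.triad @ np.array([0.0, 0.0, steps[i].rise])
        frames.append(BasePairFrame(origin, triad))
    return frames


def build_bdna(sequence: str, steps: Optional[Sequence[StepParams] | StepParams] = None) -> DNAModel:
    """Build coarse B-DNA from a top-strand sequence.

    ``steps`` may be a single StepParams applied uniformly (default: canonical
    B-DNA, 36 degree twist / 3.4 A rise) or one per base-pair step.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid base(s) {sorted(bad)} in DNA sequence")
    if len(sequence) < 2:
        raise ValueError("DNA sequence must have at least 2 bp")
    n_steps = len(sequence) - 1
    if steps is None:
        steps = StepParams()
    if isinstance(steps, StepParams):
        step_list = [steps] * n_steps
    else:
        step_list = list(steps)
        if len(step_list) != n_steps:
            raise ValueError(f"need {n_steps} step parameter sets, got {len(step_list)}")
    frames = _propagate(sequence, step_list)
    return DNAModel(sequence, frames, step_list)


def apply_site_bend(model: DNAModel, spec: BendSpec) -> DNAModel:
    """Impose per-site bends as roll increments across site footprints.

    Each footprint's steps share the site bend equally.  Bend-axis phasing
    unwinds the accumulated helical twist so the increments within one site
    compose coplanarly; see :class:`BendSpec` for cross-site phasing.
    """
    n = len(model)
    n_steps = n - 1
    bend_roll = np.zeros(n_steps)
    bend_phase = np.zeros(n_steps)

    # cumulative twist at each step, used to unwind the helical phase
    cum_twist = np.concatenate([[0.0], np.cumsum([s.twist for s in model.steps])])

    anchor = None  # phase anchor for coplanar composition across sites
    for (start, end) in sorted(spec.site_footprints):
        if start < 0 or end > n:
            raise ValueError(f"footprint [{start}, {end}) outside the {n}-bp duplex")
        site_steps = list(range(start, end - 1))
        if not site_steps:
            continue
        centre = 0.5 * (site_steps[0] + site_steps[-1])
        centre_twist = float(np.interp(centre, np.arange(n_steps + 1), cum_twist))
        if anchor is None:
            anchor = centre_twist
        ref_twist = anchor if spec.coplanar else centre_twist
        per_step = spec.per_site_bend / len(site_steps)
        for j in site_steps:
            bend_roll[j] += per_step
            # rotate the bend axis back by the twist accumulated since the
            # phase reference so all increments share one bend plane
            bend_phase[j] = ref_twist - cum_twist[j]

    frames = _propagate(model.sequence, model.steps, bend_roll, bend_phase)
    return DNAModel(model.sequence, frames, list(model.steps))


def measure_bend(model: DNAModel, end_window: int = 5) -> float:
    """Overall axis bend: angle between mean terminal local-axis vectors.

    Averages the frame z axes over the first and last ``end_window`` steps and
    returns the angle between the two means, in [0, 180] degrees.
    """
    if end_window < 1:
        raise ValueError("end_window must be >= 1")
    if len(model) < 2 * end_window + 2:
        raise ValueError(
            f"model too short: need >= {2 * end_window + 2} bp for window {end_window}"
        )
    z = np.array([f.z for f in model.frames])
    head = z[:end_window].mean(axis=0)
    tail = z[-end_window:].mean(axis=0)
    return angle_between(head, tail)


def derive_dna_restraints(
    model: DNAModel,
    *,
    distance_pad: float = 0.5,
    planarity_pad: float = 0.5,
    force_k: float = 1.0,
) -> RestraintSet:
    """Distance + planarity restraints that pin the current DNA geometry.

    Emits two-sided distance restraints between each bead and its intra-strand
    i+1 / i+2 neighbours and its inter-strand partner (targets taken from the
    model, so the set scores exactly zero on it), plus a planarity restraint
    over each stacked pair of base pairs (4 beads).
    """
    top, bottom = model.bead_coords()
    n = len(model)
    rset = RestraintSet(stage="dna")

    def dist(p, q) -> float:
        return float(np.linalg.norm(p - q))

    for chain, coords in ((TOP_CHAIN, top), (BOTTOM_CHAIN, bottom)):
        for offset in (1, 2):
            for i in range(n - offset):
                rset.add(
                    DistanceRestraint(
                        BeadId(chain, i + 1), BeadId(chain, i + 1 + offset),
                        target=dist(coords[i], coords[i + offset]),
                        lower_pad=distance_pad, upper_pad=distance_pad,
                        force_k=force_k,
                    )
                )
    for i in range(n):
        rset.add(
            DistanceRestraint(
                BeadId(TOP_CHAIN, i + 1), BeadId(BOTTOM_CHAIN, i + 1),
                target=dist(top[i], bottom[i]),
                lower_pad=distance_pad, upper_pad=distance_pad, force_k=force_k,
            )
        )
    for i in range(n - 1):
        quad = np.array([top[i], bottom[i], top[i + 1], bottom[i + 1]])
        centred = quad - quad.mean(axis=0)
        rms_now = float(np.linalg.svd(centred, compute_uv=False)[-1] / 2.0)
        # threshold = source value + pad: twisted stacked pairs are not exactly
        # coplanar, so the restraint resists further buckling without
        # penalizing the geometry it was derived from
        rset.add(
            PlanarityRestraint(
                (
                    BeadId(TOP_CHAIN, i + 1), BeadId(BOTTOM_CHAIN, i + 1),
                    BeadId(TOP_CHAIN, i + 2), BeadId(BOTTOM_CHAIN, i + 2),
                ),
                max_rms_deviation=rms_now + planarity_pad,
                force_k=force_k,
            )
        )
    return rset
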