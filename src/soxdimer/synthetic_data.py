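"""Synthetic fixtures: ideal helices, a toy HMG fold, probes, planted docking
problems, and simulated titrations.

The toy HMG fold is deliberately *not* a homology model.  Its contract is
topological: three helices in an L-shaped arrangement, residue numbering
101-184 so the mutagenesis residue lists (W115, A119, L123, L130, T138, L139,
L142, T146) resolve, and the dimerization platform residues exposed on the
outward face.  Users wanting structural realism should import a real HMG/DNA
structure in PDB format instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import BeadId, BeadSystem, ChainModel
from .docking import RigidPose
from .geometry import principal_axis, random_rotation, rotation_about_axis
from .restraints import AmbiguousRestraint, RestraintSet
from .seqtools import DuplexProbe

__all__ = [
    "ToyFoldSpec",
    "ideal_helix",
    "toy_hmg",
    "planted_docking_problem",
    "bundled_probes",
    "CC36_SEQUENCE",
    "S9WT_SEQUENCE",
    "DIMERIZATION_SEQUENCE",
    "HELIX_RISE",
    "HELIX_TWIST",
    "HELIX_RADIUS",
]

# canonical alpha-helix C-alpha geometry
HELIX_RISE = 1.5  # Angstrom per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom

#: Double-site palindromic probe (two inverted CACAAAG sites, 4 bp spacer).
CC36_SEQUENCE = "GGGATCCTACACAAAGCCGGCTTTGTGTAGGATCCC"
#: Single-site probe bearing one canonical AACAATG sequence.
S9WT_SEQUENCE = "GGGTTAACGAACAATGGAATCTGGTAGA"

#: Dimerization-region residues 71-85 (the D-peptide segment, one-letter).
DIMERIZATION_SEQUENCE = "VSIREAVSQVLSGYD"


def _helix_frame(axis_direction) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (u, v, w) with w along the helix axis."""
    w = np.asarray(axis_direction, dtype=float)
    w = w / np.linalg.norm(w)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, w)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def ideal_helix(
    sequence: str,
    start_residue: int,
    chain_id: str = "A",
    *,
    axis_start: Optional[np.ndarray] = None,
    axis_direction: Optional[np.ndarray] = None,
    phase_deg: float = 0.0,
) -> ChainModel:
    """C-alpha beads of a canonical right-handed alpha-helix.

    The helix axis runs from ``axis_start`` along ``axis_direction`` (default:
    +z from the origin); ``phase_deg`` sets the azimuth of the first residue.
    """
    n = len(sequence)
    if n < 4:
        raise ValueError("ideal helix needs at least 4 residues")
    if axis_start is None:
        axis_start = np.zeros(3)
    if axis_direction is None:
        axis_direction = np.array([0.0, 0.0, 1.0])
    axis_start = np.asarray(axis_start, dtype=float)
    u, v, w = _helix_frame(axis_direction)
    theta = np.radians(phase_deg + HELIX_TWIST * np.arange(n))
    coords = (
        axis_start[None, :]
        + HELIX_RADIUS * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
        + HELIX_RISE * np.arange(n)[:, None] * w
    )
    return ChainModel(chain_id, np.arange(start_residue, start_residue + n), coords)


@dataclass(frozen=True)
class ToyFoldSpec:
    """Layout of the toy three-helix fold.

    Helix spans are inclusive residue intervals inside the domain 101-184.
    ``angle_12`` is the angle between the alpha1 and alpha2 axes (default
    nearly antiparallel), ``angle_23`` between alpha2 and alpha3 (the L-shape
    elbow).  All axes lie in the xy-plane; the outward (platform) face points
    +z and the DNA-binding face -z.
    """

    span_1: Tuple[int, int] = (106, 125)
    span_2: Tuple[int, int] = (129, 146)
    span_3: Tuple[int, int] = (151, 170)
    angle_12: float = 165.0  # degrees between helix axes
    angle_23: float = 80.0
    first_residue: int = 101
    last_residue: int = 184

    def __post_init__(self) -> None:
        spans = [self.span_1, self.span_2, self.span_3]
        for lo, hi in spans:
            if not (self.first_residue <= lo < hi <= self.last_residue):
                raise ValueError(
                    f"helix span ({lo}, {hi}) outside domain "
                    f"{self.first_residue}-{self.last_residue}"
                )
        for (_, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 <= hi:
                raise ValueError("helix spans must be disjoint and ordered")
        for name in ("angle_12", "angle_23"):
            a = getattr(self, name)
            if not 0.0 <= a <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180] degrees")


def _extended_segment(start_point, direction, n, spacing=3.8):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return start_point + spacing * np.arange(1, n + 1)[:, None] * d


def _bridge(p_from, p_to, n):
    """n loop beads evenly spaced on the straight segment between two beads."""
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    return p_from + ts[:, None] * (np.asarray(p_to) - np.asarray(p_from))


def toy_hmg(spec: Optional[ToyFoldSpec] = None, chain_id: str = "B") -> ChainModel:
    """Toy L-shaped three-helix fold standing in for the HMG domain.

    Helices are ideal; loops and tails are extended beads.  The phases of
    alpha1 and alpha2 are chosen so the platform residues (119 on alpha1, 142
    on alpha2) point toward +z, the outward face used for dimerization-helix
    docking.
    """
    spec = spec or ToyFoldSpec()
    if spec.angle_12 in (0.0, 180.0) or spec.angle_23 in (0.0, 180.0):
        warnings.warn("degenerate inter-helix angle: helices are collinear", stacklevel=2)

    d1 = np.array([1.0, 0.0, 0.0])
    d2 = rotation_about_axis([0, 0, 1], spec.angle_12) @ d1
    d3 = rotation_about_axis([0, 0, 1], -spec.angle_23) @ d2

    n1 = spec.span_1[1] - spec.span_1[0] + 1
    n2 = spec.span_2[1] - spec.span_2[0] + 1
    n3 = spec.span_3[1] - spec.span_3[0] + 1

    # phases placing the platform residues at azimuth +z within their helices
    outward = np.array([0.0, 0.0, 1.0])

    def platform_phase(span, platform_residue, direction):
        u, v, _ = _helix_frame(direction)
        theta_out = np.degrees(np.arctan2(np.dot(outward, v), np.dot(outward, u)))
        return theta_out - HELIX_TWIST * (platform_residue - span[0])

    h1 = ideal_helix(
        "A" * n1, spec.span_1[0], chain_id,
        axis_start=np.zeros(3), axis_direction=d1,
        phase_deg=platform_phase(spec.span_1, 119, d1),
    )
    a1_end = np.zeros(3) + HELIX_RISE * (n1 - 1) * d1
    # alpha2 axis starts offset laterally from the alpha1 end so the short
    # loop can bridge and the two helices pack side by side
    a2_start = a1_end + np.array([-12.0, 11.0, 0.0])
    h2 = ideal_helix(
        "A" * n2, spec.span_2[0], chain_id,
        axis_start=a2_start, axis_direction=d2,
        phase_deg=platform_phase(spec.span_2, 142, d2),
    )
    a2_end = a2_start + HELIX_RISE * (n2 - 1) * d2
    # the alpha3 arm of the L starts far enough away for the loop to bridge
    # at near-canonical bead spacing
    loop23_n = spec.span_3[0] - spec.span_2[1] - 1
    a3_start = a2_end + (3.8 * (loop23_n + 1) + 2.0) * np.array([0.0, 1.0, 0.0]) \
        - 2.5 * np.array([1.0, 0.0, 0.0])
    h3 = ideal_helix(
        "A" * n3, spec.span_3[0], chain_id,
        axis_start=a3_start, axis_direction=d3,
        phase_deg=0.0,
    )

    # assemble: N tail, helix1, loop, helix2, loop, helix3, C tail
    pieces = []
    n_tail = spec.span_1[0] - spec.first_residue
    if n_tail:
        tail = _extended_segment(h1.coords[0], -d1, n_tail)[::-1]
        pieces.append((np.arange(spec.first_residue, spec.span_1[0]), tail))
    pieces.append((h1.residue_numbers, h1.coords))
    loop12 = spec.span_2[0] - spec.span_1[1] - 1
    if loop12:
        pieces.append(
            (
                np.arange(spec.span_1[1] + 1, spec.span_2[0]),
                _bridge(h1.coords[-1], h2.coords[0], loop12),
            )
        )
    pieces.append((h2.residue_numbers, h2.coords))
    loop23 = spec.span_3[0] - spec.span_2[1] - 1
    if loop23:
        pieces.append(
            (
                np.arange(spec.span_2[1] + 1, spec.span_3[0]),
                _bridge(h2.coords[-1], h3.coords[0], loop23),
            )
        )
    pieces.append((h3.residue_numbers, h3.coords))
    n_ctail = spec.last_residue - spec.span_3[1]
    if n_ctail:
        pieces.append(
            (
                np.arange(spec.span_3[1] + 1, spec.last_residue + 1),
                _extended_segment(h3.coords[-1], d3, n_ctail),
            )
        )
    residues = np.concatenate([p[0] for p in pieces])
    coords = np.concatenate([p[1] for p in pieces])
    return ChainModel(chain_id, residues, coords)


def _closest_axis_points(p1, d1, length1, p2, d2, length2, samples=200):
    """Closest pair of points between two finite axis segments (grid search)."""
    from scipy.spatial.distance import cdist

    t = np.linspace(0.0, 1.0, samples)
    a = p1 + np.outer(t * length1, d1)
    b = p2 + np.outer(t * length2, d2)
    d = cdist(a, b)
    i, j = np.unravel_index(int(d.argmin()), d.shape)
    return a[i], b[j]


def planted_docking_problem(
    seed: Optional[int] = None,
    *,
    contact_cutoff: float = 5.5,
    contact_gap: float = 4.05,
    min_airs: int = 9,
    mobile_chain: str = "A",
) -> Tuple[ChainModel, ChainModel, RigidPose, RestraintSet]:
    """A docking problem with a known answer.

    Plants an ideal dimerization helix in the groove between the toy HMG's
    alpha1 and alpha2 helices (the cleft that forms the dimerization
    platform), with a random slide along the groove, a random spin about its
    own axis, a random axial flip and a small random tilt.  The helix is
    lowered until the closest cross-chain bead pair sits at ``contact_gap``,
    just outside the soft-sphere clash radius, so contacts are snug.

    Ambiguous restraints are derived from the true cross-chain contacts in
    both directions (each contacting mobile residue against its receptor
    partners within ``contact_cutoff``, and vice versa) with targets equal to
    the true effective distances, so the AIR set scores exactly zero on the
    planted pose.  Placements yielding fewer than ``min_airs`` restraints are
    re-drawn: an under-constrained problem has no well-defined answer to
    recover.

    Returns ``(receptor_arm, mobile_reference, true_pose, airs)``; the mobile
    reference chain is centred at the origin and ``true_pose`` recovers the
    planted placement.
    """
    from scipy.spatial.distance import cdist

    rng = np.random.default_rng(seed)
    spec = ToyFoldSpec()
    receptor = toy_hmg()
    # the docking study uses only the alpha1/alpha2 arm that carries the
    # dimerization platform
    arm = receptor.subset(range(spec.span_1[0], spec.span_2[1] + 1))

    helix = ideal_helix(DIMERIZATION_SEQUENCE, 71, mobile_chain)
    mobile_ref = ChainModel(
        mobile_chain,
        helix.residue_numbers,
        helix.coords - helix.coords.mean(axis=0),
    )

    # groove mid-line between the two host helix axes
    d1 = np.array([1.0, 0.0, 0.0])
    n1 = spec.span_1[1] - spec.span_1[0] + 1
    n2 = spec.span_2[1] - spec.span_2[0] + 1
    d2 = rotation_about_axis([0, 0, 1], spec.angle_12) @ d1
    p1 = np.zeros(3)
    p2 = p1 + HELIX_RISE * (n1 - 1) * d1 + np.array([-12.0, 11.0, 0.0])
    a, b = _closest_axis_points(p1, d1, HELIX_RISE * (n1 - 1), p2, d2, HELIX_RISE * (n2 - 1))
    mid = 0.5 * (a + b)
    groove = d1 - d2
    groove /= np.linalg.norm(groove)
    up = np.array([0.0, 0.0, 1.0])

    for _ in range(40):
        axis_dir = groove if rng.random() < 0.5 else -groove
        tilt_axis = np.cross(up, axis_dir)
        axis_dir = rotation_about_axis(tilt_axis, float(rng.uniform(-6.0, 6.0))) @ axis_dir
        # rotation carrying the canonical +z helix axis onto axis_dir
        v = np.cross(up, axis_dir)
        if np.linalg.norm(v) < 1e-9:
            base_rot = np.eye(3) if np.dot(up, axis_dir) > 0 else rotation_about_axis([1, 0, 0], 180.0)
        else:
            ang = np.degrees(np.arctan2(np.linalg.norm(v), np.dot(up, axis_dir)))
            base_rot = rotation_about_axis(v, ang)
        rotation = rotation_about_axis(axis_dir, float(rng.uniform(0.0, 360.0))) @ base_rot
        slide = float(rng.uniform(-2.0, 2.0))
        placed0 = mobile_ref.coords @ rotation.T
        anchor = mid + slide * groove
        # bisect the height until the closest contact sits at contact_gap
        lo, hi = 0.0, 30.0
        for _ in range(50):
            z = 0.5 * (lo + hi)
            if cdist(placed0 + (anchor + z * up), arm.coords).min() < contact_gap:
                lo = z
            else:
                hi = z
        translation = anchor + hi * up
        true_pose = RigidPose(rotation, translation)

        moved = true_pose.apply(mobile_ref.coords)
        d = cdist(moved, arm.coords)
        airs = RestraintSet(stage="planted")
        for i, resid in enumerate(mobile_ref.residue_numbers):
            partners = np.where(d[i] <= contact_cutoff)[0]
            if len(partners) == 0:
                continue
            d_eff = float((d[i, partners] ** -6).sum() ** (-1.0 / 6.0))
            airs.add(
                AmbiguousRestraint(
                    group_a=(BeadId(mobile_chain, int(resid)),),
                    group_b=tuple(
                        BeadId(arm.chain_id, int(arm.residue_numbers[j])) for j in partners
                    ),
                    target=d_eff,
                )
            )
        for j, resid in enumerate(arm.residue_numbers):
            partners = np.where(d[:, j] <= contact_cutoff)[0]
            if len(partners) == 0:
                continue
            d_eff = float((d[partners, j] ** -6).sum() ** (-1.0 / 6.0))
            airs.add(
                AmbiguousRestraint(
                    group_a=(BeadId(arm.chain_id, int(resid)),),
                    group_b=tuple(
                        BeadId(mobile_chain, int(mobile_ref.residue_numbers[i]))
                        for i in partners
                    ),
                    target=d_eff,
                )
            )
        if len(airs) >= min_airs:
            return arm, mobile_ref, true_pose, airs
    raise RuntimeError("could not construct a well-constrained planted problem")


def bundled_probes() -> Dict[str, DuplexProbe]:
    """The two oligonucleotide probes used throughout, verbatim."""
    return {
        "CC36": DuplexProbe("CC36", CC36_SEQUENCE),
        "S9WT": DuplexProbe("S9WT", S9WT_SEQUENCE),
    }
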