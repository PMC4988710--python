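"""Rigid-body docking of the dimerization helix onto the HMG-domain surface.

Trials start from uniformly random orientations on a shell around the receptor
interface and are locally minimized under an energy of ambiguous interaction
restraints (AIRs) plus a soft-sphere clash penalty.  The ensemble is ranked by
energy, the best poses are clustered by the orientation of the mobile helix
relative to the receptor helices, and a representative is picked from the
predominant cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .core import BeadId, BeadSystem, ChainModel
from .geometry import angle_between, principal_axis, random_rotation
from .restraints import AmbiguousRestraint, RestraintSet

__all__ = [
    "RigidPose",
    "DockResult",
    "ClusterBin",
    "dock_trials",
    "rank_select",
    "cluster_by_orientation",
    "pick_representative",
    "CLASH_SIGMA",
]

#: Soft-sphere clash radius between cross-chain beads (Angstrom).
CLASH_SIGMA = 4.0


@dataclass(frozen=True)
class RigidPose:
    """Rigid-body transform applied to the mobile chain's reference coords."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("pose rotation must have determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class DockResult:
    pose: RigidPose
    energy: float
    trial_index: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("dock result energy must be finite")


@dataclass
class ClusterBin:
    """One orientation cluster of docked poses."""

    members: List[int]  # indices into the selected result list
    representative: int  # member index with the lowest energy
    orientation_angle: float  # leader's interhelical angle, degrees
    nn_proximal: bool  # True if N-termini of mobile and receptor helix are close


# ---------------------------------------------------------------------------
# energy machinery
# ---------------------------------------------------------------------------

class _DockEnergy:
    """Precompiled AIR + clash energy for one mobile/receptor pair."""

    def __init__(
        self,
        mobile: ChainModel,
        receptor: ChainModel,
        airs: RestraintSet,
        context: Optional[np.ndarray] = None,
    ):
        self.mobile_ref = mobile.coords.copy()
        self.receptor = receptor.coords.copy()
        if context is not None and len(context):
            # bystander coordinates (e.g. DNA, the other protein chain): they
            # contribute clash only, keeping docked poses out of occupied space
            self.obstacles = np.concatenate([self.receptor, np.asarray(context, dtype=float)])
        else:
            self.obstacles = self.receptor
        mob_index = {int(r): i for i, r in enumerate(mobile.residue_numbers)}
        rec_index = {int(r): i for i, r in enumerate(receptor.residue_numbers)}
        known = {mobile.chain_id: mob_index, receptor.chain_id: rec_index}
        self.air_terms: List[Tuple[np.ndarray, np.ndarray, float, float]] = []
        for air in airs.ambiguous:
            ia, ib = self._resolve_group(air.group_a, mobile.chain_id, known)
            ja, jb = self._resolve_group(air.group_b, mobile.chain_id, known)
            # orient so the first index array is on the mobile chain
            if ia is None and ja is None:
                raise ValueError("AIR references neither docking chain")
            mob_idx = ia if ia is not None else ja
            rec_idx = jb if ia is not None else ib
            if mob_idx is None or rec_idx is None:
                raise ValueError("each AIR group must lie on a single docking chain")
            self.air_terms.append(
                (np.asarray(mob_idx), np.asarray(rec_idx), air.target, air.force_k)
            )
        if len(self.air_terms) != len(airs.ambiguous):
            raise ValueError("AIRs must reference only the two docking chains")

    @staticmethod
    def _resolve_group(group, mobile_chain, known):
        chains = {b.chain for b in group}
        if len(chains) != 1:
            raise ValueError("AIR group spans multiple chains")
        chain = next(iter(chains))
        if chain not in known:
            raise ValueError(f"AIR group references unknown chain {chain!r}")
        idx = [known[chain][b.resid] for b in group]
        return (idx, None) if chain == mobile_chain else (None, idx)

    def batch(self, moved: np.ndarray, bias: float = 0.0) -> np.ndarray:
        """Energies of a batch of moved mobile coordinate sets, shape (k, n, 3).

        ``bias`` adds a small multiple of the summed AIR effective distances,
        used only during local search so that poses inside the flat
        zero-energy region keep sliding toward the snuggest
        restraint-satisfying contact instead of stalling at its boundary.
        """
        k_batch, n, _ = moved.shape
        d_obs = cdist(moved.reshape(-1, 3), self.obstacles).reshape(k_batch, n, -1)
        e = (np.clip(CLASH_SIGMA - d_obs, 0.0, None) ** 2).sum(axis=(1, 2))
        d = d_obs[:, :, : self.receptor.shape[0]]
        np.maximum(d, 1e-12, out=d)
        for mob_idx, rec_idx, target, k in self.air_terms:
            sub = d[:, mob_idx[:, None], rec_idx[None, :]]
            d_eff = (sub**-6).sum(axis=(1, 2)) ** (-1.0 / 6.0)
            excess = np.clip(d_eff - target, 0.0, None)
            e += k * excess * excess
            if bias:
                e += bias * d_eff
        return e

    def __call__(self, pose: RigidPose, bias: float = 0.0) -> float:
        """AIR + clash energy of one pose (see :meth:`batch`)."""
        moved = self.mobile_ref @ pose.rotation.T + pose.translation
        return float(self.batch(moved[None], bias)[0])


_AXIS_ROTS_CACHE = {}


def _rotation_about(axis_idx: int, angle: float) -> np.ndarray:
    key = (axis_idx, round(angle, 12))
    r = _AXIS_ROTS_CACHE.get(key)
    if r is None:
        c, s = np.cos(angle), np.sin(angle)
        if axis_idx == 0:
            r = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        elif axis_idx == 1:
            r = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        else:
            r = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        _AXIS_ROTS_CACHE[key] = r
    return r


def _minimize_pose(
    energy: _DockEnergy,
    pose: RigidPose,
    *,
    max_cycles: int = 200,
    trans_step: float = 4.0,
    rot_step: float = 0.5,
    shrink: float = 0.7,
    bias: float = 0.005,
) -> Tuple[RigidPose, float]:
    """Derivative-free rigid-body descent.

    Each cycle evaluates all twelve axis moves (+/- translation and +/-
    rotation about the mobile centroid, per axis) in one batch and takes the
    best improving one; step sizes are annealed by ``shrink`` whenever a full
    cycle rejects.  The search objective carries the snugness ``bias``; the
    returned energy is the pure AIR + clash score.
    """
    rot = pose.rotation.copy()
    trans = pose.translation.copy()
    centroid_ref = energy.mobile_ref.mean(axis=0)
    e = energy(RigidPose(rot, trans), bias)
    eye = np.eye(3)
    for _ in range(max_cycles):
        centre = rot @ centroid_ref + trans
        cand_rots = []
        cand_trans = []
        for axis in range(3):
            for sign in (1.0, -1.0):
                t = trans.copy()
                t[axis] += sign * trans_step
                cand_rots.append(rot)
                cand_trans.append(t)
        for axis in range(3):
            for sign in (1.0, -1.0):
                r_ax = _rotation_about(axis, sign * rot_step)
                cand_rots.append(r_ax @ rot)
                cand_trans.append(r_ax @ (trans - centre) + centre)
        moved = np.einsum(
            "nj,kij->kni", energy.mobile_ref, np.stack(cand_rots)
        ) + np.stack(cand_trans)[:, None, :]
        energies = energy.batch(moved, bias)
        best = int(np.argmin(energies))
        if energies[best] < e - 1e-12:
            rot, trans, e = cand_rots[best], cand_trans[best], float(energies[best])
        else:
            trans_step *= shrink
            rot_step *= shrink
            if trans_step < 1e-3 and rot_step < 1e-4:
                break
    # re-orthonormalize against drift from repeated rotation composition
    u, _, vt = np.linalg.svd(rot)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    final = RigidPose(rot, trans)
    return final, float(energy(final))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dock_trials(
    mobile: ChainModel,
    receptor: ChainModel,
    airs: RestraintSet,
    n_trials: int = 400,
    seed: Optional[int] = None,
    *,
    minimize_cycles: int = 200,
    context: Optional[np.ndarray] = None,
) -> List[DockResult]:
    """Run ``n_trials`` restraint-driven rigid-body docking trials.

    Each trial draws a uniform random orientation and places the mobile
    centroid at a random point on a shell around the receptor interface
    (interface radius + mobile radius + 5 A), then locally minimizes
    AIR energy + soft-sphere clash.  ``context`` passes bystander coordinates
    that contribute clash only.  Reproducible under ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    energy = _DockEnergy(mobile, receptor, airs, context)
    rng = np.random.default_rng(seed)

    # interface centre: receptor beads referenced by the AIRs (fall back to
    # the receptor centroid when no AIR names receptor beads)
    rec_idx = sorted(
        {int(i) for term in energy.air_terms for i in term[1]}
    )
    if rec_idx:
        interface = receptor.coords[rec_idx]
    else:
        interface = receptor.coords
    centre = interface.mean(axis=0)
    interface_radius = float(np.linalg.norm(interface - centre, axis=1).max())
    mob_centred = mobile.coords - mobile.coords.mean(axis=0)
    mobile_radius = float(np.linalg.norm(mob_centred, axis=1).max())
    shell = interface_radius + mobile_radius + 5.0

    results: List[DockResult] = []
    for trial in range(n_trials):
        rot = random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start_centroid = centre + shell * direction
        trans = start_centroid - rot @ mobile.coords.mean(axis=0)
        pose0 = RigidPose(rot, trans)
        pose, e = _minimize_pose(energy, pose0, max_cycles=minimize_cycles)
        results.append(DockResult(pose=pose, energy=e, trial_index=trial, seed=seed))
    return results


def rank_select(results: Sequence[DockResult], top: int = 20) -> List[DockResult]:
    """The ``top`` lowest-energy results (stable; ties broken by trial index)."""
    if not results:
        raise ValueError("no docking results to rank")
    if top > len(results):
        warnings.warn(
            f"requested top {top} of only {len(results)} results; returning all",
            stacklevel=2,
        )
        top = len(results)
    return sorted(results, key=lambda r: (r.energy, r.trial_index))[:top]


def _orientation_descriptor(
    result: DockResult,
    mobile: ChainModel,
    receptor: ChainModel,
    receptor_helix: Tuple[int, int],
) -> Tuple[float, bool]:
    """(interhelical angle, N/N-proximal flag) of one docked pose.

    Helix axes come from the principal component of each helix's beads,
    oriented from the N- to the C-terminal bead.  The flag is True when the
    mobile N-terminus sits closer to the receptor helix N-terminus than the
    C-termini are to each other — the discriminator between the two dock
    topologies.
    """
    moved = result.pose.apply(mobile.coords)
    mob_axis = principal_axis(moved, orient_along=moved[-1] - moved[0])
    lo, hi = receptor_helix
    mask = (receptor.residue_numbers >= lo) & (receptor.residue_numbers <= hi)
    helix_beads = receptor.coords[mask]
    rec_axis = principal_axis(helix_beads, orient_along=helix_beads[-1] - helix_beads[0])
    angle = angle_between(mob_axis, rec_axis)
    d_nn = float(np.linalg.norm(moved[0] - helix_beads[0]))
    d_cc = float(np.linalg.norm(moved[-1] - helix_beads[-1]))
    return angle, d_nn <= d_cc


def cluster_by_orientation(
    selected: Sequence[DockResult],
    mobile: ChainModel,
    receptor: ChainModel,
    receptor_helix: Tuple[int, int],
    angle_bin_width: float = 45.0,
) -> List[ClusterBin]:
    """Greedy leader clustering of poses on the orientation descriptor.

    A pose joins the first existing bin whose leader shares its N/N flag and
    lies within ``angle_bin_width`` degrees of interhelical angle; otherwise
    it founds a new bin.  Bins partition the input and are returned sorted by
    size (descending), ties by leader angle.
    """
    if not selected:
        raise ValueError("nothing to cluster")
    descs = [
        _orientation_descriptor(r, mobile, receptor, receptor_helix) for r in selected
    ]
    bins: List[ClusterBin] = []
    for i, (angle, nn) in enumerate(descs):
        placed = False
        for b in bins:
            if b.nn_proximal == nn and abs(angle - b.orientation_angle) <= angle_bin_width:
                b.members.append(i)
                if selected[i].energy < selected[b.representative].energy:
                    b.representative = i
                placed = True
                break
        if not placed:
            bins.append(
                ClusterBin(members=[i], representative=i, orientation_angle=angle, nn_proximal=nn)
            )
    bins.sort(key=lambda b: (-len(b.members), b.orientation_angle))
    return bins


def pick_representative(
    bins: Sequence[ClusterBin], selected: Sequence[DockResult]
) -> DockResult:
    """Lowest-energy member of the predominant (largest) orientation bin.

    Ties between equal-size bins go to the smaller orientation angle; ties
    within a bin go to the lower trial index (already encoded in ranking).
    """
    if not bins:
        raise ValueError("no cluster bins")
    best_bin = bins[0]  # bins arrive sorted by (-size, angle)
    members = sorted(
        (selected[i] for i in best_bin.members),
        key=lambda r: (r.energy, r.trial_index),
    )
    return members[0]
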