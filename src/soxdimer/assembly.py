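"""Assembly of the dimeric SOX9/DNA complex by restraint-driven annealing.

The pipeline mirrors the staged construction of the complex:

* bent tandem-site DNA with self-derived distance/planarity restraints;
* two HMG domains placed on the two inverted sites, pinned by interface
  restraints and held folded by elastic intra-domain restraints;
* N-terminal extension of each chain (dimerization region + linker) as an
  extended segment, folded into helix alpha0 by simulated annealing under
  helix restraints;
* rigid-body docking of each chain's alpha0 onto the partner HMG's platform
  under mutagenesis AIRs, followed by sampling of contact restraints from the
  chosen pose;
* one final refinement with every restraint amalgamated, the linker left
  unrestrained (bonded terms only).

Energies are reduced units: flat-bottom restraints (k = 1 per A^2), harmonic
bonds, and a soft-sphere clash term.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .core import BOND_LENGTH, HARD_CLASH, BeadId, BeadSystem, ChainModel
from .dna_model import (
    BendSpec,
    DNAModel,
    apply_site_bend,
    build_bdna,
    derive_dna_restraints,
    measure_bend,
)
from .docking import (
    CLASH_SIGMA,
    DockResult,
    cluster_by_orientation,
    dock_trials,
    pick_representative,
    rank_select,
)
from .geometry import dihedral as _dihedral_func
from .restraints import (
    AmbiguousRestraint,
    DistanceRestraint,
    PlanarityRestraint,
    RestraintSet,
    TorsionRestraint,
    helix_restraints,
    make_airs,
    sample_contact_restraints,
)
from .seqtools import (
    FACE_RESIDUES_DEFAULT,
    DuplexProbe,
    MotifPattern,
    PLATFORM_RESIDUES_DEFAULT,
    ProteinRegion,
    SiteHit,
    scan_motif,
)
from .synthetic_data import (
    CC36_SEQUENCE,
    DIMERIZATION_SEQUENCE,
    ToyFoldSpec,
    toy_hmg,
)

__all__ = [
    "AnnealSchedule",
    "AssemblyConfig",
    "ComplexModel",
    "anneal",
    "place_hmg_on_dna",
    "assemble_dimer",
    "validate_model",
]

#: soft-sphere radius for non-bonded bead pairs during annealing (Angstrom);
#: smaller than the docking sigma because bonded chains pack closer
ANNEAL_CLASH_SIGMA = 3.0
K_BOND = 10.0
#: bonds are flat-bottomed around the canonical C-alpha spacing so that a
#: relaxed chain exerts no residual pull against flat-bottom restraints
BOND_PAD = 0.2
K_CLASH = 1.0
#: torsion restraints act in degrees; scale them to the A^2 energy scale
K_TORSION = 0.02

AIR_PASSIVE_DEFAULT = (115, 123, 130, 138, 139, 146)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for Metropolis Monte-Carlo refinement."""

    start_temp: float = 50.0
    end_temp: float = 0.5
    n_stages: int = 8
    steps_per_stage: int = 2000
    move_amplitude: float = 0.5  # Angstrom, base single-bead displacement
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start_temp <= self.end_temp:
            raise ValueError("start temperature must exceed end temperature")
        if self.end_temp <= 0:
            raise ValueError("temperatures must be positive")
        if self.n_stages < 1 or self.steps_per_stage < 1:
            raise ValueError("stage counts must be >= 1")

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.start_temp, self.end_temp, self.n_stages)


# ---------------------------------------------------------------------------
# annealing engine
# ---------------------------------------------------------------------------

class _AnnealEngine:
    """Incremental energy bookkeeping for single-bead Metropolis moves.

    Restraints are compiled to flat-index terms; per-move deltas touch only
    the terms involving the moved bead plus its bond and clash partners.
    Terms none of whose beads are movable contribute a constant, computed
    once.
    """

    def __init__(
        self,
        system: BeadSystem,
        restraints: RestraintSet,
        movable: Optional[Set[BeadId]] = None,
        bonded_chains: Optional[Set[str]] = None,
        extra_active: Set[BeadId] = frozenset(),
    ):
        self.system = system
        self.coords, self.ids, self.index = system.flatten()
        n = len(self.ids)
        all_ids = set(self.ids)
        if movable is None:
            movable = all_ids
        missing = (movable | set(extra_active)) - all_ids
        if missing:
            raise KeyError(f"movable beads not in system: {sorted(missing)[:3]}")
        self.movable_idx = np.array(sorted(self.index[b] for b in movable), dtype=int)
        active = movable | set(extra_active)

        # bonds: consecutive residues of each bonded (protein) chain
        if bonded_chains is None:
            bonded_chains = set(system.chains)
        self.bond_partners: List[List[int]] = [[] for _ in range(n)]
        for cid in bonded_chains:
            chain = system.chains[cid]
            order = np.argsort(chain.residue_numbers)
            res_sorted = chain.residue_numbers[order]
            for a, b in zip(res_sorted, res_sorted[1:]):
                if b == a + 1:
                    i = self.index[BeadId(cid, int(a))]
                    j = self.index[BeadId(cid, int(b))]
                    self.bond_partners[i].append(j)
                    self.bond_partners[j].append(i)

        # clash exclusion: self + bonded neighbours
        self.clash_excl: List[np.ndarray] = [
            np.array([i] + self.bond_partners[i], dtype=int) for i in range(n)
        ]

        # compile restraint terms
        self.terms: List[tuple] = []
        self.bead_terms: List[List[int]] = [[] for _ in range(n)]
        movable_flat = {self.index[b] for b in active}
        self.constant_energy = 0.0
        for r in restraints:
            idx = self._compile(r)
            term_beads = self._term_beads(idx)
            if movable_flat.isdisjoint(term_beads):
                self.constant_energy += self._term_energy_raw(idx, self.coords)
                continue
            t_i = len(self.terms)
            self.terms.append(idx)
            for b in term_beads:
                self.bead_terms[b].append(t_i)

    def _compile(self, r) -> tuple:
        ix = self.index
        if isinstance(r, AmbiguousRestraint):
            ga = np.array([ix[b] for b in r.group_a], dtype=int)
            gb = np.array([ix[b] for b in r.group_b], dtype=int)
            return ("air", ga, gb, r.target, r.force_k)
        if isinstance(r, DistanceRestraint):
            return (
                "dist", ix[r.bead_a], ix[r.bead_b], r.target,
                r.lower_pad, r.upper_pad, r.force_k, r.upper_only,
            )
        if isinstance(r, TorsionRestraint):
            beads = tuple(ix[b] for b in r.beads_abcd)
            return ("tors", beads, r.target, r.half_width, r.force_k)
        if isinstance(r, PlanarityRestraint):
            beads = np.array([ix[b] for b in r.bead_group], dtype=int)
            return ("plan", beads, r.max_rms_deviation, r.force_k)
        raise TypeError(f"cannot compile restraint {type(r)!r}")

    @staticmethod
    def _term_beads(idx: tuple) -> List[int]:
        kind = idx[0]
        if kind == "air":
            return [*idx[1].tolist(), *idx[2].tolist()]
        if kind == "dist":
            return [idx[1], idx[2]]
        if kind == "tors":
            return list(idx[1])
        return idx[1].tolist()

    def _term_energy_raw(self, idx: tuple, coords: np.ndarray) -> float:
        kind = idx[0]
        if kind == "dist":
            _, i, j, target, lo, hi, k, upper_only = idx
            d = float(np.linalg.norm(coords[i] - coords[j]))
            dev = d - target
            if dev > hi:
                x = dev - hi
            elif dev < -lo and not upper_only:
                x = -dev - lo
            else:
                return 0.0
            return k * x * x
        if kind == "air":
            _, ga, gb, target, k = idx
            d = cdist(coords[ga], coords[gb])
            if np.any(d == 0.0):
                d_eff = 0.0
            else:
                d_eff = float((d**-6).sum() ** (-1.0 / 6.0))
            x = max(0.0, d_eff - target)
            return k * x * x
        if kind == "tors":
            _, beads, target, half, k = idx
            obs = _dihedral_func(*(coords[b] for b in beads))
            dev = (obs - target + 180.0) % 360.0 - 180.0
            x = max(0.0, abs(dev) - half)
            return K_TORSION * k * x * x
        _, beads, max_rms, k = idx
        pts = coords[beads]
        centred = pts - pts.mean(axis=0)
        rms = float(np.linalg.svd(centred, compute_uv=False)[-1] / np.sqrt(len(pts)))
        x = max(0.0, rms - max_rms)
        return k * x * x

    # -- per-bead local energy -------------------------------------------
    def bead_local_energy(self, i: int) -> float:
        coords = self.coords
        e = 0.0
        for t in self.bead_terms[i]:
            e += self._term_energy_raw(self.terms[t], coords)
        for j in self.bond_partners[i]:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            x = max(0.0, abs(d - BOND_LENGTH) - BOND_PAD)
            e += K_BOND * x * x
        diff = coords - coords[i]
        d_all = np.sqrt((diff * diff).sum(axis=1))
        d_all[self.clash_excl[i]] = np.inf
        overlap = ANNEAL_CLASH_SIGMA - d_all
        np.clip(overlap, 0.0, None, out=overlap)
        e += K_CLASH * float((overlap * overlap).sum())
        return e

    def group_energy(self, group: np.ndarray, group_set: set) -> float:
        """Energy of terms touching a bead group, for rigid-segment moves.

        Terms are evaluated once each; intra-group pair contributions are
        invariant under rigid motion and may be included (they cancel in the
        move delta).  Clash counts group-vs-outside pairs only.
        """
        coords = self.coords
        e = 0.0
        seen: set = set()
        for i in group:
            for t in self.bead_terms[i]:
                if t not in seen:
                    seen.add(t)
                    e += self._term_energy_raw(self.terms[t], coords)
        for i in group:
            for j in self.bond_partners[i]:
                if j in group_set and j < i:
                    continue  # intra-group bond counted once (cancels anyway)
                d = float(np.linalg.norm(coords[i] - coords[j]))
                x = max(0.0, abs(d - BOND_LENGTH) - BOND_PAD)
                e += K_BOND * x * x
        d = cdist(coords[group], coords)
        for row, i in enumerate(group):
            d[row, self.clash_excl[i]] = np.inf
        d[:, list(group_set)] = np.inf  # intra-group pairs are rigid-invariant
        overlap = np.clip(ANNEAL_CLASH_SIGMA - d, 0.0, None)
        e += K_CLASH * float((overlap**2).sum())
        return e

    def total_energy(self) -> float:
        coords = self.coords
        e = self.constant_energy
        for idx in self.terms:
            e += self._term_energy_raw(idx, coords)
        for i in range(len(coords)):
            for j in self.bond_partners[i]:
                if j > i:
                    dist = float(np.linalg.norm(coords[i] - coords[j]))
                    x = max(0.0, abs(dist - BOND_LENGTH) - BOND_PAD)
                    e += K_BOND * x * x
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        for i in range(len(coords)):
            d[i, self.clash_excl[i]] = np.inf
        overlap = np.clip(ANNEAL_CLASH_SIGMA - d, 0.0, None)
        e += 0.5 * K_CLASH * float((overlap**2).sum())
        return e

    def writeback(self) -> None:
        self.system.set_flat_coords(self.coords)


def _polish(
    engine: "_AnnealEngine",
    groups: Sequence[Tuple[np.ndarray, set]] = (),
    steps: Sequence[float] = (0.1, 0.03, 0.01),
    max_sweeps: int = 60,
) -> None:
    """Deterministic coordinate descent: axis-wise bead (and rigid-group)
    moves accepted only when they lower the energy.  Polishes the sub-pad
    violations that finite-temperature Monte-Carlo leaves behind."""
    from .geometry import rotation_about_axis

    axes = np.eye(3)
    for _ in range(max_sweeps):
        improved = False
        for i in engine.movable_idx:
            e0 = engine.bead_local_energy(i)
            if e0 <= 0.0:
                continue
            old = engine.coords[i].copy()
            best_e, best_pos = e0, None
            for step in steps:
                for ax in range(3):
                    for sign in (1.0, -1.0):
                        engine.coords[i] = old + sign * step * axes[ax]
                        e = engine.bead_local_energy(i)
                        if e < best_e - 1e-12:
                            best_e, best_pos = e, engine.coords[i].copy()
            engine.coords[i] = best_pos if best_pos is not None else old
            improved = improved or best_pos is not None
        for gidx, gset in groups:
            e0 = engine.group_energy(gidx, gset)
            old = engine.coords[gidx].copy()
            centre = old.mean(axis=0)
            best_e, best_pos = e0, None
            for step in (0.1, 0.02):
                for ax in range(3):
                    for sign in (1.0, -1.0):
                        engine.coords[gidx] = old + sign * step * axes[ax]
                        e = engine.group_energy(gidx, gset)
                        if e < best_e - 1e-12:
                            best_e, best_pos = e, engine.coords[gidx].copy()
            for ang in (0.5, 0.1):
                for ax in range(3):
                    for sign in (1.0, -1.0):
                        rot = rotation_about_axis(axes[ax], sign * ang)
                        engine.coords[gidx] = (old - centre) @ rot.T + centre
                        e = engine.group_energy(gidx, gset)
                        if e < best_e - 1e-12:
                            best_e, best_pos = e, engine.coords[gidx].copy()
            engine.coords[gidx] = best_pos if best_pos is not None else old
            improved = improved or best_pos is not None
        if not improved:
            break


def anneal(
    system: BeadSystem,
    restraints: RestraintSet,
    schedule: AnnealSchedule,
    *,
    movable: Optional[Set[BeadId]] = None,
    bonded_chains: Optional[Set[str]] = None,
    rigid_groups: Sequence[Set[BeadId]] = (),
    rigid_move_prob: float = 0.2,
    polish: bool = False,
) -> Tuple[BeadSystem, List[float]]:
    """Metropolis Monte-Carlo refinement under restraints + bonds + clash.

    Moves are single-bead Gaussian displacements over the ``movable`` beads
    (default: all), with amplitude scaled with temperature, plus optional
    rigid-segment moves (small rotation + translation of each ``rigid_groups``
    member, e.g. a folded helix).  Returns the refined system (a copy) and the
    per-stage energy trace of the active restraint terms; bonded and clash
    terms enter the acceptance test.  Reproducible under ``schedule.seed``.
    """
    from .geometry import rotation_about_axis

    work = system.copy()
    group_beads: Set[BeadId] = set().union(*rigid_groups) if rigid_groups else set()
    engine = _AnnealEngine(work, restraints, movable, bonded_chains,
                           extra_active=group_beads)
    if len(engine.movable_idx) == 0 and not rigid_groups:
        raise ValueError("no movable beads")
    rng = np.random.default_rng(schedule.seed)
    groups = []
    for g in rigid_groups:
        idx = np.array(sorted(engine.index[b] for b in g), dtype=int)
        groups.append((idx, set(idx.tolist())))
    trace: List[float] = []
    n_mov = len(engine.movable_idx)
    for temp in schedule.temperatures():
        # displacement amplitude tracks temperature: wide exploration when
        # hot, sub-pad refinement moves when cold
        amp = float(np.clip(schedule.move_amplitude * math.sqrt(temp), 0.02, 2.0))
        for _ in range(schedule.steps_per_stage):
            if groups and (n_mov == 0 or rng.random() < rigid_move_prob):
                gidx, gset = groups[rng.integers(len(groups))]
                old = engine.coords[gidx].copy()
                e_before = engine.group_energy(gidx, gset)
                centre = old.mean(axis=0)
                axis = rng.normal(size=3)
                angle = float(rng.normal(0.0, 2.0 * math.sqrt(temp)))
                rot = rotation_about_axis(axis, angle)
                shift = rng.normal(0.0, 0.3 * amp, 3)
                engine.coords[gidx] = (old - centre) @ rot.T + centre + shift
                delta = engine.group_energy(gidx, gset) - e_before
                if delta > 0 and rng.random() >= math.exp(-delta / temp):
                    engine.coords[gidx] = old
                continue
            i = int(engine.movable_idx[rng.integers(n_mov)])
            old_bead = engine.coords[i].copy()
            e_before = engine.bead_local_energy(i)
            engine.coords[i] = old_bead + rng.normal(0.0, amp, 3)
            delta = engine.bead_local_energy(i) - e_before
            if delta > 0 and rng.random() >= math.exp(-delta / temp):
                engine.coords[i] = old_bead  # reject
        stage_e = sum(engine._term_energy_raw(t, engine.coords) for t in engine.terms)
        trace.append(float(stage_e + engine.constant_energy))
    if polish:
        _polish(engine, groups)
        stage_e = sum(engine._term_energy_raw(t, engine.coords) for t in engine.terms)
        trace.append(float(stage_e + engine.constant_energy))
    engine.writeback()
    return work, trace


# ---------------------------------------------------------------------------
# HMG placement on DNA
# ---------------------------------------------------------------------------

def _site_frame(dna: DNAModel, site: SiteHit):
    """Base-pair frame at the site centre; minus-strand sites get the
    dyad-flipped frame (x, -y, -z) so placement is strand-symmetric."""
    centre = (site.start + site.end - 1) // 2
    if site.start < 0 or site.end > len(dna):
        raise ValueError(f"site [{site.start}, {site.end}) outside {len(dna)}-bp DNA")
    f = dna.frames[centre]
    x, y, z = f.x, f.y, f.z
    if site.strand == "-":
        y, z = -y, -z
    return f.origin, x, y, z


def place_hmg_on_dna(
    hmg: ChainModel,
    dna: DNAModel,
    site: SiteHit,
    *,
    standoff: float = 11.0,
    axial_shift: float = -3.0,
    interface_cutoff: float = 12.0,
    pad: float = 0.5,
    anchor_residues: Tuple[int, int] = (106, 146),
) -> Tuple[ChainModel, RestraintSet]:
    """Place an HMG chain at a binding site, binding face toward the DNA.

    The toy fold's local frame (platform face +z, alpha1 axis +x) is mapped so
    its binding face (-z) points at the site centre from the minor-groove side
    and its arm runs along the local DNA axis.  The placement is anchored on
    the centroid of ``anchor_residues`` (the alpha1/alpha2 arm that contacts
    the DNA), offset ``standoff`` Angstrom from the site centre.  Emits
    two-sided protein-DNA distance restraints for all bead pairs within
    ``interface_cutoff`` (targets from the placed geometry, so they score zero
    on it).
    """
    origin, x, y, z = _site_frame(dna, site)
    # minor groove side: -x of the base-pair frame.  The arm axis maps to -z
    # (antiparallel to the local DNA axis) so the N-terminal tail of each
    # placed domain points at the partner site of the inverted repeat.
    local = np.stack([-z, np.cross(-x, -z), -x], axis=1)  # columns: image of x,y,z
    if np.linalg.det(local) < 0:
        local[:, 1] = -local[:, 1]
    arm_mask = (hmg.residue_numbers >= anchor_residues[0]) & (
        hmg.residue_numbers <= anchor_residues[1]
    )
    if not arm_mask.any():
        raise ValueError("anchor residues absent from the HMG chain")
    centre_ref = hmg.coords[arm_mask].mean(axis=0)
    # axial_shift < 0 slides the domain along the site-local DNA axis away
    # from the inverted partner site, keeping the two placed domains apart
    placed_coords = (
        (hmg.coords - centre_ref) @ local.T + origin - standoff * x + axial_shift * z
    )
    placed = ChainModel(hmg.chain_id, hmg.residue_numbers.copy(), placed_coords)

    top, bottom = dna.bead_coords()
    dna_chains = dna.to_chains()
    rset = RestraintSet(stage="interface")
    for dchain, dcoords in zip(dna_chains, (top, bottom)):
        d = cdist(placed.coords, dcoords)
        if float(d.min()) < HARD_CLASH:
            raise ValueError("HMG placement clashes with DNA")
        ii, jj = np.where(d <= interface_cutoff)
        for i, j in zip(ii, jj):
            rset.add(
                DistanceRestraint(
                    BeadId(placed.chain_id, int(placed.residue_numbers[i])),
                    BeadId(dchain.chain_id, int(dchain.residue_numbers[j])),
                    target=float(d[i, j]),
                    lower_pad=pad,
                    upper_pad=pad,
                )
            )
    if not rset.distances:
        raise ValueError("placement produced no interface contacts; increase cutoff")
    return placed, rset


def _scaffold_restraints(
    chain: ChainModel, cutoff: float = 10.0, pad: float = 0.5, stage: str = "scaffold"
) -> RestraintSet:
    """Elastic-network distance restraints that hold a domain's fold."""
    d = cdist(chain.coords, chain.coords)
    rset = RestraintSet(stage=stage)
    n = len(chain)
    for i in range(n):
        for j in range(i + 2, n):
            if d[i, j] <= cutoff:
                rset.add(
                    DistanceRestraint(
                        BeadId(chain.chain_id, int(chain.residue_numbers[i])),
                        BeadId(chain.chain_id, int(chain.residue_numbers[j])),
                        target=float(d[i, j]),
                        lower_pad=pad,
                        upper_pad=pad,
                    )
                )
    return rset


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyConfig:
    """Configuration of the end-to-end dimer assembly."""

    probe_top_strand: str = CC36_SEQUENCE
    motif: str = "CACAAAG"
    per_site_bend: float = 54.0  # degrees per site; two sites compose to 108
    coplanar_bend: bool = True
    dimer_region_start: int = 71
    helix_span: Tuple[int, int] = (72, 84)
    linker_span: Tuple[int, int] = (86, 100)
    hmg_start: int = 101
    face_residues: Tuple[int, ...] = tuple(sorted(FACE_RESIDUES_DEFAULT))
    platform_residues: Tuple[int, ...] = tuple(sorted(PLATFORM_RESIDUES_DEFAULT))
    passive_residues: Tuple[int, ...] = AIR_PASSIVE_DEFAULT
    n_dock_trials: int = 400
    dock_top: int = 20
    n_contact_restraints: int = 50
    contact_cutoff: float = 10.0
    cis_dimerization: bool = False  # dock alpha0 onto its own HMG instead
    #: with the mutagenesis AIRs switched off there is no attractive term and
    #: the docking/contact stages are skipped: alpha0 stays near its own chain
    use_dimerization_airs: bool = True
    fold_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(50.0, 0.2, 8, 6000, 0.4)
    )
    linker_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(3.0, 0.05, 4, 4000, 0.4)
    )
    final_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(0.5, 0.01, 8, 6000, 0.25)
    )
    # effectively greedy descent: polishes residual sub-pad violations left
    # by the finite-temperature stages
    quench_schedule: AnnealSchedule = field(
        default_factory=lambda: AnnealSchedule(1e-4, 1e-7, 3, 20000, 0.3)
    )
    seed: Optional[int] = 0


@dataclass
class ComplexModel:
    """The assembled dimeric protein/DNA complex."""

    proteins: Dict[str, ChainModel]
    dna: DNAModel
    restraints: RestraintSet
    provenance: Dict[str, object] = field(default_factory=dict)

    def system(self) -> BeadSystem:
        sys = BeadSystem.from_chains(self.proteins.values())
        for chain in self.dna.to_chains():
            sys.add(chain)
        return sys


def _arc_bridge(p_from: np.ndarray, p_to: np.ndarray, n: int, away: np.ndarray,
                spacing: float = BOND_LENGTH) -> np.ndarray:
    """``n`` beads on a circular arc from ``p_from`` to ``p_to``.

    The arc bulges along ``away`` just enough that consecutive beads sit near
    ``spacing``, so a freshly bridged linker starts with sane bond lengths
    instead of a compressed straight line.
    """
    p_from = np.asarray(p_from, dtype=float)
    p_to = np.asarray(p_to, dtype=float)
    chord = p_to - p_from
    away = np.asarray(away, dtype=float)
    away = away - np.dot(away, chord) / max(np.dot(chord, chord), 1e-12) * chord
    nrm = np.linalg.norm(away)
    if nrm < 1e-9:
        ref = np.array([0.0, 0.0, 1.0])
        away = np.cross(chord, ref)
        if np.linalg.norm(away) < 1e-9:
            away = np.cross(chord, [0.0, 1.0, 0.0])
        nrm = np.linalg.norm(away)
    away /= nrm
    target_len = spacing * (n + 1)
    ts = np.linspace(0.0, 1.0, n + 2)

    def polyline(h):
        pts = p_from + ts[:, None] * chord + (h * np.sin(np.pi * ts))[:, None] * away
        return pts, float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    lo, hi = 0.0, target_len
    if polyline(0.0)[1] < target_len:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if polyline(mid)[1] < target_len:
                lo = mid
            else:
                hi = mid
    pts, _ = polyline(0.5 * (lo + hi))
    return pts[1:-1]


def _extension_ids(cfg: AssemblyConfig, chain_id: str) -> Set[BeadId]:
    return {
        BeadId(chain_id, r)
        for r in range(cfg.dimer_region_start, cfg.hmg_start)
    }


def _extend_nterm(chain: ChainModel, cfg: AssemblyConfig, away: np.ndarray) -> ChainModel:
    """Prepend the dimerization region + linker as an extended segment."""
    away = away / np.linalg.norm(away)
    first = chain.coords[0]
    n_ext = cfg.hmg_start - cfg.dimer_region_start
    ext = first + BOND_LENGTH * np.arange(1, n_ext + 1)[:, None] * away
    ext = ext[::-1]  # residue 71 farthest out
    residues = np.concatenate(
        [np.arange(cfg.dimer_region_start, cfg.hmg_start), chain.residue_numbers]
    )
    coords = np.concatenate([ext, chain.coords])
    return ChainModel(chain.chain_id, residues, coords)


def assemble_dimer(cfg: Optional[AssemblyConfig] = None) -> Tuple[ComplexModel, Dict]:
    """Run the full staged assembly; returns the complex and a report.

    The report carries the measured DNA bend, restraint-violation summary,
    linker end-to-end spans, cross-chain dimerization-helix contact counts,
    and the per-stage seeds used.
    """
    cfg = cfg or AssemblyConfig()
    master = random.Random(cfg.seed)
    stage_seed = {name: master.randrange(2**31) for name in
                  ("fold", "dock_a", "dock_b", "contacts_a", "contacts_b",
                   "fold_quench", "linker", "final", "quench")}
    report: Dict[str, object] = {"seeds": dict(stage_seed), "stages": []}

    # ---- stage: DNA -----------------------------------------------------
    probe = DuplexProbe("probe", cfg.probe_top_strand)
    hits = scan_motif(probe, MotifPattern(cfg.motif))
    if len(hits) != 2:
        raise ValueError(
            f"stage dna: expected 2 motif sites on the probe, found {len(hits)}"
        )
    dna = build_bdna(probe.top_strand)
    spec = BendSpec(
        tuple((h.start, h.end) for h in hits), cfg.per_site_bend, cfg.coplanar_bend
    )
    dna = apply_site_bend(dna, spec)
    dna_restraints = derive_dna_restraints(dna)
    report["stages"].append("dna")

    # ---- stage: HMG placement ------------------------------------------
    all_restraints = RestraintSet(stage="amalgamated")
    all_restraints.extend(dna_restraints)
    proteins: Dict[str, ChainModel] = {}
    own_site = {}
    for chain_id, hit in zip(("A", "B"), hits):
        hmg = toy_hmg(chain_id=chain_id)
        placed, interface = place_hmg_on_dna(hmg, dna, hit)
        proteins[chain_id] = placed
        own_site[chain_id] = hit
        all_restraints.extend(interface)
        all_restraints.extend(_scaffold_restraints(placed))
    report["stages"].append("placement")

    # ---- stage: extension + helix folding ------------------------------
    dna_axis_mid = dna.frames[len(dna) // 2].origin
    helix_sets = {}
    for chain_id in ("A", "B"):
        chain = proteins[chain_id]
        away = chain.coords.mean(axis=0) - dna_axis_mid
        proteins[chain_id] = _extend_nterm(chain, cfg, away)
        region = ProteinRegion(
            DIMERIZATION_SEQUENCE[
                cfg.helix_span[0] - cfg.dimer_region_start :
                cfg.helix_span[1] - cfg.dimer_region_start + 1
            ],
            cfg.helix_span[0],
        )
        helix_sets[chain_id] = helix_restraints(region, chain_id)
        all_restraints.extend(helix_sets[chain_id])

    system = BeadSystem.from_chains(proteins.values())
    for chain in dna.to_chains():
        system.add(chain)

    movable = _extension_ids(cfg, "A") | _extension_ids(cfg, "B")
    fold_sched = replace(cfg.fold_schedule, seed=stage_seed["fold"])
    system, fold_trace = anneal(
        system, all_restraints, fold_sched,
        movable=movable, bonded_chains={"A", "B"},
    )
    # quench the fresh fold so the helix sits inside every flat bottom before
    # its pose is frozen into sampled contact restraints
    fold_quench = replace(cfg.quench_schedule, seed=stage_seed["fold_quench"])
    system, _ = anneal(
        system, all_restraints, fold_quench,
        movable=movable, bonded_chains={"A", "B"},
    )
    report["fold_energy_trace"] = [round(e, 3) for e in fold_trace]
    report["stages"].append("fold_alpha0")

    # ---- stage: dock alpha0 on the partner HMG --------------------------
    partner = {"A": "B", "B": "A"} if not cfg.cis_dimerization else {"A": "A", "B": "B"}
    toy_spec = ToyFoldSpec()
    alpha0_res = range(cfg.dimer_region_start, cfg.linker_span[0])
    contact_sets = {}
    dock_chains = ("A", "B") if cfg.use_dimerization_airs else ()
    for chain_id in dock_chains:
        rec_id = partner[chain_id]
        receptor_chain = system.chains[rec_id].subset(
            range(toy_spec.span_1[0], toy_spec.span_2[1] + 1)
        )
        mobile = system.chains[chain_id].subset(alpha0_res)
        airs = make_airs(
            list(cfg.face_residues), list(cfg.platform_residues),
            list(cfg.passive_residues),
            chain_a=chain_id, chain_b=rec_id, stage=f"airs_{chain_id}",
        )
        arm_set = set(range(toy_spec.span_1[0], toy_spec.span_2[1] + 1))
        a0_set = set(alpha0_res)
        context_parts = []
        for cid, c in system.chains.items():
            if cid == rec_id:
                mask = ~np.isin(c.residue_numbers, sorted(arm_set))
            elif cid == chain_id:
                # own HMG is an obstacle; the linker will be re-bridged
                mask = c.residue_numbers >= cfg.hmg_start
            else:
                mask = np.ones(len(c), dtype=bool)
            if mask.any():
                context_parts.append(c.coords[mask])
        context = np.concatenate(context_parts)
        results = dock_trials(
            mobile, receptor_chain, airs,
            n_trials=cfg.n_dock_trials,
            seed=stage_seed[f"dock_{chain_id.lower()}"],
            context=context,
        )
        best = rank_select(results, cfg.dock_top)
        bins = cluster_by_orientation(best, mobile, receptor_chain, toy_spec.span_1)
        rep = pick_representative(bins, best)
        report[f"dock_{chain_id}"] = {
            "bins": [len(b.members) for b in bins],
            "representative_energy": round(rep.energy, 4),
        }
        # write the docked alpha0 back and re-bridge the linker
        docked = rep.pose.apply(mobile.coords)
        chain = system.chains[chain_id]
        a0_mask = np.isin(chain.residue_numbers, list(alpha0_res))
        chain.coords[a0_mask] = docked
        l_lo, l_hi = cfg.linker_span
        p_from = chain.bead_coord(l_lo - 1)
        p_to = chain.bead_coord(cfg.hmg_start)
        n_link = l_hi - l_lo + 1
        away = 0.5 * (p_from + p_to) - dna_axis_mid
        link_mask = (chain.residue_numbers >= l_lo) & (chain.residue_numbers <= l_hi)
        chain.coords[link_mask] = _arc_bridge(p_from, p_to, n_link, away)

        contact_sets[chain_id] = sample_contact_restraints(
            system, chain_id, rec_id,
            n=cfg.n_contact_restraints, cutoff=cfg.contact_cutoff,
            seed=stage_seed[f"contacts_{chain_id.lower()}"],
            residues_a=alpha0_res,
            residues_b=range(cfg.hmg_start, 185),
            stage=f"contacts_{chain_id}",
        )
        all_restraints.extend(contact_sets[chain_id])
    report["stages"].append("dock_alpha0")

    # ---- stage: amalgamated final refinement ----------------------------
    # the freshly bridged linkers are relaxed first (everything else held),
    # then the whole extension refines under the amalgamated restraints;
    # the linker carries only bonded terms: no restraint references it
    l_lo, l_hi = cfg.linker_span
    linker_ids = {
        BeadId(cid, r) for cid in ("A", "B") for r in range(l_lo, l_hi + 1)
    }
    linker_sched = replace(cfg.linker_schedule, seed=stage_seed["linker"])
    system, _ = anneal(
        system, all_restraints, linker_sched,
        movable=linker_ids, bonded_chains={"A", "B"},
    )
    final_sched = replace(cfg.final_schedule, seed=stage_seed["final"])
    alpha0_groups = [
        {BeadId(cid, r) for r in alpha0_res} for cid in ("A", "B")
    ]
    system, final_trace = anneal(
        system, all_restraints, final_sched,
        movable=movable, bonded_chains={"A", "B"},
        rigid_groups=alpha0_groups,
    )
    quench_sched = replace(cfg.quench_schedule, seed=stage_seed["quench"])
    system, quench_trace = anneal(
        system, all_restraints, quench_sched,
        movable=movable, bonded_chains={"A", "B"},
        rigid_groups=alpha0_groups, polish=True,
    )
    report["final_energy_trace"] = [round(e, 3) for e in final_trace + quench_trace]
    report["stages"].append("final_refinement")

    for chain_id in ("A", "B"):
        proteins[chain_id] = system.chains[chain_id]
    model = ComplexModel(
        proteins={cid: system.chains[cid] for cid in ("A", "B")},
        dna=dna,
        restraints=all_restraints,
        provenance={"config_seed": cfg.seed, "seeds": stage_seed,
                    "stages": list(report["stages"])},
    )
    metrics = validate_model(model)
    report["metrics"] = metrics
    report["alpha0_docked"] = (
        metrics["alpha0_cross_contacts"]["A"] > 0
        and metrics["alpha0_cross_contacts"]["B"] > 0
    )
    return model, report


def validate_model(model: ComplexModel) -> Dict[str, object]:
    """Deterministic quality metrics of an assembled complex."""
    system = model.system()
    total, violations = model.restraints.evaluate(system)
    n_rest = len(model.restraints)
    max_violation = violations[0].excess if violations else 0.0
    bend = measure_bend(model.dna)
    linker_spans = {}
    alpha0_contacts = {}
    partner = {"A": "B", "B": "A"}
    for cid, chain in model.proteins.items():
        lo = chain.residue_numbers.min()
        if lo < 101:
            p86 = chain.bead_coord(86)
            p100 = chain.bead_coord(100)
            linker_spans[cid] = float(np.linalg.norm(p100 - p86))
            a0 = chain.subset(range(71, 86))
            other = model.proteins[partner[cid]]
            hmg_other = other.subset(range(101, 185))
            d = cdist(a0.coords, hmg_other.coords)
            alpha0_contacts[cid] = int((d <= 8.0).sum())
    return {
        "bend_degrees": float(bend),
        "restraint_energy": float(total),
        "n_restraints": n_rest,
        "n_violated": len(violations),
        "satisfied_fraction": 1.0 - (len(violations) / n_rest if n_rest else 0.0),
        "max_violation_A": float(max_violation),
        "clash_count": system.clash_count(),
        "linker_spans_A": linker_spans,
        "alpha0_cross_contacts": alpha0_contacts,
    }
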