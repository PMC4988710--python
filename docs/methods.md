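# Methods

`soxdimer` models how SOX Group E transcription factors (SOX8/9/10) dimerize
on DNA: two HMG domains bind a pair of inverted heptamer sites, and a short
amphipathic helix (the dimerization helix, called alpha0 here, residues
72-84 of SOX9) N-terminal to each HMG domain reaches across and docks onto a
hydrophobic platform (A119/L142 and their neighbours) on the *partner* HMG
domain.  The package covers three layers of that problem: sequence/motif
analysis, gel-shift (EMSA) quantitation, and a coarse-grained restraint-based
assembly of the dimeric protein/DNA complex.

## Sequence analysis

Probes are stored as a top strand only; the bottom strand is always the
reverse complement.  Motif scanning matches an IUPAC-degenerate pattern
against every window of the top strand and, independently, against the
reverse complement of the pattern (a minus-strand hit), counting per-position
mismatches with no indels.  Hit coordinates are 0-based half-open on the top
strand, which makes site spacing the plain difference `right.start -
left.end`.

The helical wheel assigns residue *i* of a region the azimuth
`(i - first) * 100 degrees (mod 360)` — the canonical alpha-helical 100
degrees per residue; the rate is configurable.  The hydrophobic alphabet
defaults to {A, V, I, L, M, F, W, Y}; glycine, proline and cysteine are
treated as non-face-forming.  Face detection finds the smallest circular arc
covering all hydrophobic residues (the complement of the largest angular gap;
ties go to the smaller arc start) and reports whether that arc excludes every
other residue — the operational definition of a clean amphipathic
separation.  Phenotype prediction for substitution mutants is positional: a
substitution at a face residue {73, 76, 77, 80, 81, 84} or a platform residue
{119, 142} is called a loss of dimerization, assayed-neutral positions
{78, 79, 118, 145} are called retained, and anything else is unknown.

## EMSA quantitation

Bound-band intensities, normalized to the highest protein concentration, are
fit to the four-parameter logistic curve

    AB = d + (a - d) / (1 + (B / Kd)^b)

with lower/upper asymptotes *a*, *d*, midpoint *Kd* (nM) and steepness *b*
(the Hill coefficient).  The fit is nonlinear least squares
(Levenberg-Marquardt via `scipy.optimize.least_squares`) with *Kd* and *b*
parameterized on a log scale for conditioning; starting values are
`a = min(y)`, `d = max(y)`, `Kd = geometric mid of the concentration grid`,
`b = 1`.  Tolerances are 1e-12 on parameter/function change with a cap of
2000 function evaluations, and the convergence flag is propagated rather
than silenced.  Standard errors come from the Gauss-Newton curvature
`(J'J)^-1 * RSS/dof`, delta-method-transformed back to the linear scale.
The constant probe concentration is carried along and a warning is emitted
when it exceeds Kd/5, where the apparent Kd begins to deviate from the true
one; the model itself assumes probe << Kd.

The titration simulator evaluates the same forward model and adds i.i.d.
Gaussian read-out noise (default grid: 12 log-spaced points over 10-450 nM,
the refined experimental range; noise s.d. 0.03 of the dynamic range in the
recovery tests).  Kinetics are the literal identities `k_off = ln2 / t_half`
and `k_on = k_off / Kd`; both are pure arithmetic with input validation, and
the package intentionally reports what the formulas give rather than any
rounded literature figure.  Band-pattern classification calls a mutant
dimerizing when, at sub-stoichiometric protein:DNA ratios, the
singly-occupied band is essentially absent (fraction < 0.05 by default)
while the doubly-occupied band is populated.

## Coarse-grained representation

Proteins are one bead per residue at the C-alpha position; DNA is one frame
per base pair (orthonormal triad: x into the major groove, z along the local
helix axis) with two beads per pair at +/-4.5 A along the frame y axis,
approximating the phosphate positions.  Frames are propagated by composing
per-step twist/roll/tilt rotations (defaults 36 deg twist, 3.4 A rise —
canonical B-DNA) with the rise translation.

A site-directed bend distributes a per-site roll increment uniformly over the
steps of a binding-site footprint.  The bend axis at each step is the local
y axis unwound by the helical twist accumulated since a phase reference, so
the increments within one site compose in a single plane.  By default the
phase reference is shared across sites (anchored at the first site's centre,
`coplanar=True`), which makes multi-site bends compose additively: two
54-degree sites give a 108-degree overall bend regardless of their helical
phasing.  With `coplanar=False` each site bends in its own centre-frame
plane and the composition depends on the twist between sites.  The coplanar
default was chosen because the quantity of interest is the overall bend of
the assembled two-site complex; per-site groove-directed phasing is retained
as an option.

Bend measurement averages the frame z axes over the first and last
`end_window` (default 5) steps and reports the angle between the two means.
This windowed-axis definition is a package choice — short duplexes do not
support stable curve-fitting of a global axis — and it is exact on
single-rotation test cases.

DNA self-restraints pin the built geometry: two-sided distance restraints
bead-to-(i+1, i+2) along each strand and to the paired bead across strands
(targets copied from the model, pads +/-0.5 A), plus a planarity restraint
over each stacked quartet of beads.  Because twisted stacked pairs are not
exactly coplanar, each planarity threshold is set to the source geometry's
own RMS plane deviation plus the 0.5 A pad, so every derived set scores
exactly zero on the model it came from and resists buckling beyond it.

## Restraint energies

All restraints are flat-bottom harmonics: zero inside a tolerance band,
`k * excess^2` outside, with `k = 1` per A^2 in reduced units unless stated.
Distance restraints are two-sided; hydrogen-bond-type restraints and
ambiguous interaction restraints (AIRs) penalize only the upper side.  An
AIR between bead groups is evaluated on the r^-6-summed effective distance
`(sum_ij d_ij^-6)^(-1/6)`, which is never larger than the closest pair, so
any one close contact satisfies it.  The conventional 2.0 A atom-scale AIR
target is mapped to bead resolution by a +3.0 A calibration offset (C-alpha
beads of contacting residues cannot approach to 2 A); the 5.0 A bead target
is an explicit documented constant.  Torsion restraints act on the C-alpha
pseudo-dihedral with wrap-aware deviations; their force constant is scaled
by 0.02 when mixed into the annealing energy so that degree-scale and
Angstrom-scale violations are comparable.

Helix restraints encode canonical alpha-helix geometry: a pseudo-torsion
restraint of +50 +/- 10 degrees per 4-residue window and upper-bound i->i+3
(5.1 A) and i->i+4 (6.2 A) distances with 0.3 A pads — an ideal helix
(1.5 A rise, 100 deg/residue, 2.3 A radius) satisfies all of them with
margin.  Mutagenesis AIRs are one per dimerization-face residue against the
combined active {119, 142} + passive {115, 123, 130, 138, 139, 146} platform
surface.  Contact-restraint sampling draws n pairs uniformly without
replacement from the cross-chain pairs within a cutoff, after sorting the
eligible list lexicographically, so a seed reproduces the same sample on any
platform; targets are the current distances (pad 0.5 A), making the emitted
set zero-energy on its source pose by construction.

## Docking

Rigid-body docking minimizes `E = AIR energy + soft-sphere clash`
(`sum max(0, 4.0 - d)^2` over cross-chain bead pairs; bystander coordinates
such as DNA enter the clash term only).  Each of the 400 trials starts from
a uniform random rotation (uniform-quaternion method) with the mobile
centroid on a shell of radius interface-radius + mobile-radius + 5 A around
the AIR-defined receptor interface.  Local minimization is derivative-free
rigid-body descent: every cycle evaluates all twelve axis moves (+/-
translation and +/- rotation about the mobile centroid per axis) in one
vectorized batch and takes the best improving move; on a rejected cycle both
step sizes shrink by 0.7 from 4.0 A / 0.5 rad down to convergence, within a
200-cycle budget.  The search objective adds a small snugness bias
(0.005 x summed AIR effective distances): inside the flat zero-energy region
of upper-bound-only restraints the pure energy has no gradient, and without
the bias a minimizer stalls at the first feasible pose rather than the
snuggest one.  Reported energies are always the pure AIR + clash score.

The selected low-energy poses are leader-clustered on an orientation
descriptor: the interhelical angle between the mobile helix axis and the
receptor alpha1 axis (principal components oriented N-to-C) plus a flag for
whether the N-termini or the C-termini of the two helices are the proximal
pair.  A pose joins the first bin whose leader shares its flag and lies
within 45 degrees; bins are reported by size, and the representative is the
lowest-energy member of the largest bin (ties: smaller leader angle, then
lower trial index).  The number of bins is emergent, not fixed.

## Assembly pipeline

`assemble_dimer` runs the stages in order, all seeds derived from one master
seed and recorded in the report:

1. **DNA** — scan the probe for the two inverted sites, build B-DNA, apply
   the per-site bend (default 54 degrees per site, coplanar, so the two-site
   model bends 108 degrees overall), derive the DNA self-restraints.
2. **Placement** — put one toy HMG fold on each site: the binding face
   toward the site centre from the minor-groove side, the helix arm
   antiparallel to the local DNA axis so each domain's N-terminal tail
   points at the partner site, anchored 11 A from the site centre with a
   3 A axial offset away from the partner (keeps the two domains from
   touching).  Minus-strand sites use the dyad-flipped frame (x, -y, -z),
   which makes the two placements exact images under the palindrome
   two-fold.  Interface restraints (all protein-DNA bead pairs within 12 A,
   targets from the placed geometry) and an elastic network over each domain
   (intra-chain pairs within 10 A) pin everything that follows.
3. **Extension and folding** — residues 71-100 are prepended as an extended
   segment pointing away from the DNA; simulated annealing under the helix
   restraints folds 72-84 into a helix, followed by a near-zero-temperature
   quench so the folded helix sits strictly inside every flat bottom before
   its pose is frozen into sampled restraints.
4. **Docking** — each chain's alpha0 (71-85) is rigid-body docked onto the
   partner's alpha1/alpha2 arm under the mutagenesis AIRs, with every other
   bead in the system as clash context.  The representative pose is written
   back, the linker (86-100) re-bridged as a circular arc sized for
   near-canonical bead spacing, and 50 contact restraints sampled between
   alpha0 and the partner HMG domain (residues 101-184 only — the partner's
   own flexible extension is never a restraint anchor).
5. **Final refinement** — the linker is first relaxed alone, then all
   restraints are amalgamated and the extensions refine under Metropolis
   Monte-Carlo (0.5 -> 0.01 reduced temperature, 8 geometric stages of 6000
   steps) with single-bead moves plus rigid-segment moves of each alpha0
   helix, a greedy quench, and a deterministic axis-wise polish.  The linker
   carries bonded terms only — no restraint references residues 86-100 —
   implementing the unrestrained-linker choice literally.  The HMG domains
   and the DNA are held at their restrained stage-2/3 geometry during this
   pass: their restraints are identically satisfied by construction, so
   annealing them would add noise without information.

The annealing energy is restraints + bonds + clash.  Bonds between
consecutive residues are flat-bottom harmonics (3.8 +/- 0.2 A, k = 10): the
flat bottom matters, because a plain harmonic exerts a residual pull at any
bond length and that pull drags the docked helix permanently off its
contact-zero pose, leaving a frustrated floor of small violations.
Non-bonded clash is `sum max(0, 3.0 - d)^2` (smaller than the 4.0 A docking
sigma — bonded chains pack closer); the hard-clash metric reported by
`validate_model` counts cross-chain pairs under 2.5 A.  Move amplitudes
scale with sqrt(temperature), clipped to [0.02, 2.0] A, so hot stages
explore and cold stages make sub-pad refinements.

## Synthetic data

The generators supply every geometry the pipeline needs without downloads:

* `ideal_helix` — canonical C-alpha helix (1.5 A rise/residue,
  100 deg/residue, 2.3 A radius, right-handed: pseudo-torsion +50 deg).
* `toy_hmg` — an L-shaped three-helix fold on residues 101-184 with spans
  alpha1 106-125, alpha2 129-146, alpha3 151-170, chosen so all the
  mutagenesis residues (W115, A119, L123, L130, T138, L139, L142, T146)
  resolve and the platform residues point to the outward (+z) face, more
  than 8 A from the alpha3 axis.  It is a topological stand-in, not a
  homology model: helix lengths, loop paths and the overall dimensions are
  not those of a real HMG domain, so absolute distances in the assembled
  complex (linker spans, domain separations) characterize the toy geometry
  only.  Users wanting realism can read a real structure through the PDB
  reader, which collapses all-atom files to C-alpha/P beads.
* `planted_docking_problem` — a docking problem with a withheld answer: the
  dimerization helix is planted in the alpha1/alpha2 groove (random slide,
  spin, axial flip and small tilt) and lowered until the closest cross-chain
  pair sits at 4.05 A, just outside the clash radius, so the contacts are
  snug.  AIRs are derived bidirectionally from the true contacts within
  5.5 A with targets equal to the true effective distances (zero-energy at
  the truth); placements producing fewer than 9 AIRs are re-drawn, because
  an under-constrained problem has no recoverable answer.  The snug gap and
  the tight bidirectional targets are what make the zero-energy region
  compact enough for 2 A-level recovery; upper-bound-only restraints on a
  convex surface patch would leave a feasible set many Angstroms wide.
* `bundled_probes` — the CC36 and S9WT oligonucleotide sequences verbatim.
  The single-site probe is described in its source as 29 bp but the printed
  sequence has 28 nt; the package uses the printed sequence as-is.

What passing tests show — and do not show.  The recovery, clustering and
assembly checks demonstrate that the restraint engine, the docking search
and the annealer do what they claim on geometry whose ground truth is known.
They do not validate the biological accuracy of the final model: the toy
fold's platform location is imposed, the AIR residue lists come from the
mutagenesis data, and no energetics beyond excluded volume are modelled.

## Problem sizes and determinism

Default sizes: 12-point titrations; 36-bp duplex; 400 docking trials with
the 20 best retained; 50 sampled contacts per chain; annealing schedules of
8 geometric stages (folding 50 -> 0.2, final 0.5 -> 0.01) at a few thousand
single-bead moves per stage.  A full default assembly runs in a few minutes
on one CPU.  Every stochastic component takes an explicit seed; the
assembly derives per-stage seeds from one master seed and records them in
the report, so any run is bit-reproducible from its report alone.

## Known limitations

* One bead per residue carries no side-chain identity: hydrophobicity enters
  only through which residues are restrained, never through the energy.
* No electrostatics, desolvation or sequence-dependent DNA mechanics; the
  bend magnitude is configuration, not prediction.
* The 4PL is a phenomenological binding curve; it does not resolve the
  two-site occupancy thermodynamics that the band-pattern classifier reads
  out qualitatively.
* Kinetic back-calculation assumes a single-exponential dissociation and
  diffusion-free interpretation of k_on = k_off/Kd.
* The linker is modelled as a freely jointed bead chain; its reported spans
  bound what the real 15-residue linker could bridge but do not model its
  conformational ensemble.
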