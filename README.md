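# soxdimer

Sequence analysis, gel-shift quantitation and coarse-grained restraint-based
modelling of DNA-dependent dimerization of SOX Group E transcription factors.

SOX8, SOX9 and SOX10 bind DNA through an HMG domain and, uniquely within the
SOX family, dimerize on promoters carrying two inverted `(A/T)(A/T)CAA(A/T)G`
sites.  The dimerization signal lives in a short region N-terminal to the HMG
domain that behaves as a single amphipathic helix (residues 72-84 in SOX9,
called α0): substitutions on its hydrophobic face, or at two surface residues
of the HMG domain (A119, L142), abolish dimerization.  This package is for
structural/quantitative biologists who want to work with that system at desk
scale: scan probes for binding sites, fit binding titrations, and build a
bead-level model of the dimeric protein/DNA complex in which each chain's α0
helix docks onto the *partner* HMG domain across a bent tandem site.

## What is inside

| module | what it does |
|---|---|
| `soxdimer.seqtools` | IUPAC motif scanning of duplex probes (both strands), palindrome and site-spacing checks, helical-wheel projection, hydrophobic-face detection, rule-based dimerization-phenotype calls |
| `soxdimer.emsa` | four-parameter logistic (4PL) fitting of EMSA titrations `AB = d + (a-d)/(1+(B/Kd)^b)`, titration simulation, kinetics (`k_off = ln2/t½`, `k_on = k_off/Kd`), band-pattern classification |
| `soxdimer.dna_model` | coarse B-DNA from base-pair step parameters, site-directed bends as phased roll increments, overall bend measurement, DNA self-restraints |
| `soxdimer.restraints` | flat-bottom distance/torsion/planarity restraints, ambiguous interaction restraints (AIRs) with the r⁻⁶ effective distance, helix restraints, mutagenesis AIRs, contact sampling, TSV serialization |
| `soxdimer.docking` | AIR-driven rigid-body docking (400 random-start trials, derivative-free descent), energy ranking, orientation clustering, representative selection |
| `soxdimer.assembly` | Metropolis simulated annealing and the staged assembly of the full dimeric complex |
| `soxdimer.synthetic_data` | ideal helices, a toy three-helix HMG fold, planted docking problems with known answers, the bundled CC36/S9WT probes |
| `soxdimer.io` / `soxdimer.cli` | FASTA/PDB/CSV/TSV readers and writers, validated run configuration, the `soxdimer` command |

## Worked example

Scan the bundled two-site probe and check its geometry:

```bash
$ soxdimer scan --probe CC36 --motif CACAAAG
probe CC36 (36 bp), palindromic: True
  [  9,  16)  strand +  CACAAAG
  [ 20,  27)  strand -  CTTTGTG
site spacing: 4 bp
```

The probe is a 36-bp palindrome with one heptamer site per strand and 4 bp
between the footprints — the substrate geometry for a SOX9 dimer.

Fit a (simulated, noisy) titration of the dimerizing fragment on that probe:

```bash
$ soxdimer fit4pl --table titration.csv
a  = -0.0098 +/- 0.0090
d  = 0.9943 +/- 0.0120
Kd = 95.91 +/- 1.53 nM
b  = 4.656 +/- 0.298 (Hill coefficient)
converged: True
```

The midpoint (Kd ≈ 96 nM here) estimates the apparent affinity; a Hill
coefficient well above 2 is the signature of cooperative double-site filling
by the dimer.  Back-calculate rates from a dissociation half-life:

```bash
$ soxdimer kinetics --half-life 600 --kd-nm 98
k_off = 0.001155 1/s
k_on  = 1.179e+04 1/(M s)
```

Assemble the full dimeric complex on the two-site probe:

```bash
$ soxdimer assemble --seed 0 --out model.pdb --report report.json
model -> model.pdb, report -> report.json
bend 108.0 deg, restraints satisfied 100.0%, clashes 0
```

The report (JSON) records, for this run: DNA bend 108.0°, all 1121 restraints
satisfied, zero hard clashes, 68 and 72 cross-chain α0→HMG contacts for the
two chains, and linker spans of 30.1 Å and 41.8 Å — both comfortably inside
what a 15-residue linker can bridge (57 Å).  The bend is the composition of
the two configured 54° site bends; the cross-chain contacts are the *trans*
architecture in which each dimerization helix sits on the partner domain.
The model PDB (chains A/B protein as CA beads, C/D DNA as P beads) opens in
any structure viewer.

The same pipeline is available as a library:

```python
from soxdimer import AssemblyConfig, assemble_dimer
model, report = assemble_dimer(AssemblyConfig(seed=0))
print(report["metrics"]["bend_degrees"])   # 108.0
```

`docs/methods.md` describes the models, energies, defaults and their
limitations.

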