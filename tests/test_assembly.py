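"""Annealing engine, HMG placement and the staged dimer assembly."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from soxdimer.assembly import (
    AnnealSchedule,
    AssemblyConfig,
    ComplexModel,
    anneal,
    assemble_dimer,
    place_hmg_on_dna,
    validate_model,
)
from soxdimer.core import BeadId, BeadSystem, ChainModel
from soxdimer.dna_model import build_bdna
from soxdimer.geometry import kabsch_rmsd
from soxdimer.restraints import DistanceRestraint, RestraintSet, helix_restraints
from soxdimer.seqtools import MotifPattern, ProteinRegion, SiteHit, scan_motif
from soxdimer.synthetic_data import CC36_SEQUENCE, bundled_probes, ideal_helix, toy_hmg

#: small schedules keep the refinement tests fast; the full defaults are
#: exercised by the end-to-end acceptance checks
FAST = AssemblyConfig(
    n_dock_trials=30,
    fold_schedule=AnnealSchedule(50.0, 0.2, 6, 3000, 0.4),
    linker_schedule=AnnealSchedule(3.0, 0.05, 3, 2500, 0.4),
    final_schedule=AnnealSchedule(0.5, 0.01, 6, 3000, 0.25),
    quench_schedule=AnnealSchedule(1e-4, 1e-7, 2, 8000, 0.3),
    seed=0,
)


class TestAnneal:
    def test_no_restraints_leaves_chain_near_input(self):
        chain = ideal_helix("SIREAVSQVLSGY", 72, "A")
        system = BeadSystem.from_chains([chain])
        sched = AnnealSchedule(0.5, 0.1, 2, 500, 0.2, seed=1)
        out, _ = anneal(system, RestraintSet(), sched)
        disp = np.linalg.norm(out.chains["A"].coords - chain.coords, axis=1)
        assert disp.max() < 3.0
        bonds = np.linalg.norm(np.diff(out.chains["A"].coords, axis=0), axis=1)
        assert bonds.min() > 2.8 and bonds.max() < 4.8

    def test_satisfiable_restraints_relax_toward_witness(self):
        # the ideal helix is a witness configuration for its own restraints;
        # starting from an extended chain the annealer must approach it
        region = ProteinRegion("SIREAVSQVLSGY", 72)
        rset = helix_restraints(region, "A")
        coords = np.zeros((13, 3))
        coords[:, 0] = 3.8 * np.arange(13)
        extended = ChainModel("A", np.arange(72, 85), coords)
        system = BeadSystem.from_chains([extended])
        e_init, _ = rset.evaluate(system)
        sched = AnnealSchedule(50.0, 0.05, 8, 5000, 0.4, seed=3)
        out, trace = anneal(system, rset, sched)
        e_final, _ = rset.evaluate(out)
        assert e_final < 0.01 * e_init
        assert trace[-1] <= trace[0]

    def test_same_seed_gives_identical_endpoint(self):
        chain = ideal_helix("SIREAVSQVLSGY", 72, "A")
        system = BeadSystem.from_chains([chain])
        rset = helix_restraints(ProteinRegion("SIREAVSQVLSGY", 72), "A")
        sched = AnnealSchedule(5.0, 0.1, 3, 1000, 0.3, seed=42)
        out1, _ = anneal(system, rset, sched)
        out2, _ = anneal(system, rset, sched)
        assert np.array_equal(out1.chains["A"].coords, out2.chains["A"].coords)

    def test_unresolvable_restraint_fails_before_any_move(self):
        chain = ideal_helix("SIREAVSQVLSGY", 72, "A")
        system = BeadSystem.from_chains([chain])
        rset = RestraintSet()
        rset.add(DistanceRestraint(BeadId("A", 72), BeadId("Q", 1), 5.0))
        with pytest.raises(KeyError):
            anneal(system, rset, AnnealSchedule(5.0, 0.1, 2, 100, 0.3, seed=0))


class TestPlacement:
    @pytest.fixture
    def straight_dna(self):
        return build_bdna(CC36_SEQUENCE)

    def test_interface_restraints_score_zero_on_own_pose(self, straight_dna):
        hits = scan_motif(bundled_probes()["CC36"], MotifPattern("CACAAAG"))
        placed, interface = place_hmg_on_dna(toy_hmg(chain_id="A"), straight_dna, hits[0])
        system = BeadSystem.from_chains([placed, *straight_dna.to_chains()])
        total, _ = interface.evaluate(system)
        assert total == 0.0
        assert len(interface.distances) > 0

    def test_placement_does_not_clash_with_dna(self, straight_dna):
        hits = scan_motif(bundled_probes()["CC36"], MotifPattern("CACAAAG"))
        placed, _ = place_hmg_on_dna(toy_hmg(chain_id="A"), straight_dna, hits[0])
        top, bottom = straight_dna.bead_coords()
        d = cdist(placed.coords, np.vstack([top, bottom]))
        assert d.min() > 2.5

    def test_two_placements_related_by_palindrome_dyad(self, straight_dna):
        """On a straight palindromic duplex the two site placements must be
        images of each other under the duplex two-fold axis."""
        hits = scan_motif(bundled_probes()["CC36"], MotifPattern("CACAAAG"))
        placed_a, _ = place_hmg_on_dna(toy_hmg(chain_id="A"), straight_dna, hits[0])
        placed_b, _ = place_hmg_on_dna(toy_hmg(chain_id="B"), straight_dna, hits[1])
        top, bottom = straight_dna.bead_coords()
        # the dyad swaps the strands and reverses base order
        set1 = np.vstack([top, bottom, placed_a.coords])
        set2 = np.vstack([bottom[::-1], top[::-1], placed_b.coords])
        assert kabsch_rmsd(set1, set2) < 1.0

    def test_site_out_of_range_rejected(self, straight_dna):
        bad = SiteHit(33, 7, "+", "CACAAAG")
        with pytest.raises(ValueError, match="outside"):
            place_hmg_on_dna(toy_hmg(chain_id="A"), straight_dna, bad)


@pytest.fixture(scope="module")
def assembled():
    return assemble_dimer(FAST)


class TestAssembleDimer:
    def test_report_metrics_present(self, assembled):
        _, report = assembled
        metrics = report["metrics"]
        for key in ("bend_degrees", "satisfied_fraction", "clash_count",
                    "linker_spans_A", "alpha0_cross_contacts"):
            assert key in metrics

    def test_bend_matches_configured_composition(self, assembled):
        model, report = assembled
        assert report["metrics"]["bend_degrees"] == pytest.approx(108.0, abs=5.0)

    def test_linker_spans_within_extension_bound(self, assembled):
        _, report = assembled
        for span in report["metrics"]["linker_spans_A"].values():
            assert span <= 15 * 3.8

    def test_trans_architecture(self, assembled):
        _, report = assembled
        contacts = report["metrics"]["alpha0_cross_contacts"]
        assert contacts["A"] > 0 and contacts["B"] > 0
        assert report["alpha0_docked"]

    def test_no_hard_clashes(self, assembled):
        _, report = assembled
        assert report["metrics"]["clash_count"] == 0

    def test_seed_recorded_and_deterministic(self, assembled):
        _, report = assembled
        _, report2 = assemble_dimer(FAST)
        assert report["seeds"] == report2["seeds"]
        assert report["metrics"] == report2["metrics"]

    def test_without_dimerization_airs_alpha0_is_not_docked(self):
        from dataclasses import replace

        cfg = replace(FAST, use_dimerization_airs=False)
        _, report = assemble_dimer(cfg)
        assert not report["alpha0_docked"]


class TestValidateModel:
    def test_straight_dna_complex_has_zero_bend(self):
        dna = build_bdna(CC36_SEQUENCE)
        chain = toy_hmg(chain_id="A")
        chain = ChainModel("A", chain.residue_numbers, chain.coords + [0, 60.0, 0])
        model = ComplexModel({"A": chain}, dna, RestraintSet())
        metrics = validate_model(model)
        assert metrics["bend_degrees"] == pytest.approx(0.0, abs=1e-6)

    def test_known_violation_reported_exactly(self):
        dna = build_bdna(CC36_SEQUENCE)
        chain = toy_hmg(chain_id="A")
        chain = ChainModel("A", chain.residue_numbers, chain.coords + [0, 60.0, 0])
        rset = RestraintSet()
        d_now = float(np.linalg.norm(chain.bead_coord(101) - chain.bead_coord(120)))
        # target displaced 10.5 A beyond the current distance, pad 0.5
        rset.add(DistanceRestraint(BeadId("A", 101), BeadId("A", 120),
                                   target=d_now + 10.5, lower_pad=0.5, upper_pad=0.5))
        model = ComplexModel({"A": chain}, dna, rset)
        metrics = validate_model(model)
        assert metrics["max_violation_A"] == pytest.approx(10.0)
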