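"""Flat-bottom restraint energies, AIR semantics and restraint synthesis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soxdimer.core import BeadId, BeadSystem, ChainModel
from soxdimer.geometry import rotation_about_axis
from soxdimer.restraints import (
    AmbiguousRestraint,
    DistanceRestraint,
    HBondRestraint,
    PlanarityRestraint,
    RestraintSet,
    TorsionRestraint,
    effective_distance,
    helix_restraints,
    make_airs,
    sample_contact_restraints,
)
from soxdimer.seqtools import ProteinRegion
from soxdimer.synthetic_data import DIMERIZATION_SEQUENCE, ideal_helix


def two_chain_system(coords_a, coords_b):
    return BeadSystem.from_chains(
        [
            ChainModel("A", np.arange(1, len(coords_a) + 1), np.array(coords_a, float)),
            ChainModel("B", np.arange(1, len(coords_b) + 1), np.array(coords_b, float)),
        ]
    )


class TestEffectiveDistance:
    def test_single_pair_equals_plain_distance(self):
        sys_ = two_chain_system([[0, 0, 0]], [[5, 0, 0]])
        air = AmbiguousRestraint((BeadId("A", 1),), (BeadId("B", 1),))
        assert effective_distance(air, sys_) == pytest.approx(5.0)

    def test_two_equal_pairs_closed_form(self):
        sys_ = two_chain_system([[0, 0, 0]], [[5, 0, 0], [-5, 0, 0]])
        air = AmbiguousRestraint((BeadId("A", 1),), (BeadId("B", 1), BeadId("B", 2)))
        assert effective_distance(air, sys_) == pytest.approx(5.0 * 2 ** (-1 / 6))

    def test_shortest_pair_dominates(self):
        sys_ = two_chain_system([[0, 0, 0]], [[3, 0, 0], [100, 0, 0]])
        air = AmbiguousRestraint((BeadId("A", 1),), (BeadId("B", 1), BeadId("B", 2)))
        assert effective_distance(air, sys_) == pytest.approx(3.0, abs=1e-4)

    def test_coincident_beads_defined_as_zero(self):
        sys_ = two_chain_system([[0, 0, 0]], [[0, 0, 0]])
        air = AmbiguousRestraint((BeadId("A", 1),), (BeadId("B", 1),))
        assert effective_distance(air, sys_) == 0.0

    @given(
        ds=st.lists(st.floats(min_value=1.0, max_value=50.0), min_size=1, max_size=6)
    )
    def test_never_exceeds_minimum_pairwise_distance(self, ds):
        coords_b = [[d, 0, 0] for d in ds]
        sys_ = two_chain_system([[0, 0, 0]], coords_b)
        air = AmbiguousRestraint(
            (BeadId("A", 1),), tuple(BeadId("B", i + 1) for i in range(len(ds)))
        )
        assert effective_distance(air, sys_) <= min(ds) + 1e-9


class TestEvaluate:
    def test_flat_bottom_formula(self):
        sys_ = two_chain_system([[0, 0, 0]], [[7, 0, 0]])
        r = DistanceRestraint(BeadId("A", 1), BeadId("B", 1), target=5.0,
                              lower_pad=0.5, upper_pad=0.5, force_k=1.0)
        rset = RestraintSet(distances=[r])
        total, violations = rset.evaluate(sys_)
        assert total == pytest.approx(1.5**2)
        assert violations[0].excess == pytest.approx(1.5)

    def test_inside_pads_is_zero(self):
        sys_ = two_chain_system([[0, 0, 0]], [[5.4, 0, 0]])
        r = DistanceRestraint(BeadId("A", 1), BeadId("B", 1), target=5.0)
        total, violations = RestraintSet(distances=[r]).evaluate(sys_)
        assert total == 0.0 and violations == []

    def test_hbond_penalizes_upper_side_only(self):
        close = two_chain_system([[0, 0, 0]], [[2.0, 0, 0]])
        far = two_chain_system([[0, 0, 0]], [[9.0, 0, 0]])
        r = HBondRestraint(BeadId("A", 1), BeadId("B", 1), target=5.0)
        assert RestraintSet(distances=[r]).evaluate(close)[0] == 0.0
        assert RestraintSet(distances=[r]).evaluate(far)[0] > 0

    def test_unresolvable_bead_names_the_bead(self):
        sys_ = two_chain_system([[0, 0, 0]], [[5, 0, 0]])
        r = DistanceRestraint(BeadId("Z", 9), BeadId("B", 1), target=5.0)
        with pytest.raises(KeyError, match="Z:9"):
            RestraintSet(distances=[r]).evaluate(sys_)

    def test_energy_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        coords_a = rng.normal(size=(6, 3)) * 5
        coords_b = rng.normal(size=(5, 3)) * 5 + 8
        sys_ = two_chain_system(coords_a, coords_b)
        rset = RestraintSet()
        rset.add(DistanceRestraint(BeadId("A", 1), BeadId("B", 2), target=4.0))
        rset.add(AmbiguousRestraint((BeadId("A", 3),), (BeadId("B", 1), BeadId("B", 4))))
        rset.add(TorsionRestraint(tuple(BeadId("A", i) for i in (1, 2, 3, 4)), 50.0))
        rset.add(PlanarityRestraint(tuple(BeadId("B", i) for i in (1, 2, 3, 4)), 0.1))
        e0, _ = rset.evaluate(sys_)
        rot = rotation_about_axis([1, 1, 0], 123.0)
        shift = np.array([-4.0, 9.0, 2.0])
        moved = two_chain_system(coords_a @ rot.T + shift, coords_b @ rot.T + shift)
        e1, _ = rset.evaluate(moved)
        assert e1 == pytest.approx(e0, rel=1e-9, abs=1e-12)


class TestHelixRestraints:
    def test_window_counts_for_13mer(self):
        region = ProteinRegion("SIREAVSQVLSGY", 72)
        rset = helix_restraints(region, "A")
        assert len(rset.torsions) == 10
        i3 = [r for r in rset.distances if r.bead_b.resid - r.bead_a.resid == 3]
        i4 = [r for r in rset.distances if r.bead_b.resid - r.bead_a.resid == 4]
        assert len(i3) == 10 and len(i4) == 9

    def test_ideal_helix_scores_zero(self):
        helix = ideal_helix("SIREAVSQVLSGY", 72, "A")
        rset = helix_restraints(ProteinRegion("SIREAVSQVLSGY", 72), "A")
        total, _ = rset.evaluate(BeadSystem.from_chains([helix]))
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_extended_chain_scores_high(self):
        coords = np.zeros((13, 3))
        coords[:, 0] = 3.8 * np.arange(13)
        chain = ChainModel("A", np.arange(72, 85), coords)
        rset = helix_restraints(ProteinRegion("SIREAVSQVLSGY", 72), "A")
        total, violations = rset.evaluate(BeadSystem.from_chains([chain]))
        assert total > 100
        assert violations

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            helix_restraints(ProteinRegion("SIRE", 72), "A")


class TestMakeAirs:
    def test_default_mutagenesis_lists(self):
        rset = make_airs(
            [73, 76, 77, 80, 81, 84], [119, 142],
            [115, 123, 130, 138, 139, 146],
        )
        assert len(rset.ambiguous) == 6
        for air in rset.ambiguous:
            assert len(air.group_b) == 8
            assert air.target == pytest.approx(5.0)

    def test_single_pair(self):
        rset = make_airs([73], [119])
        assert len(rset.ambiguous) == 1
        air = rset.ambiguous[0]
        assert len(air.group_a) == 1 and len(air.group_b) == 1

    def test_empty_active_list_rejected(self):
        with pytest.raises(ValueError, match="active_a"):
            make_airs([], [119])

    def test_same_chain_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            make_airs([73], [73, 119], chain_a="A", chain_b="A")


class TestSampledContacts:
    @pytest.fixture
    def contact_system(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(20, 3)) * 3.0
        b = rng.normal(size=(20, 3)) * 3.0 + [4.0, 0, 0]
        return two_chain_system(a, b)

    def test_emitted_set_scores_zero_on_source_pose(self, contact_system):
        rset = sample_contact_restraints(contact_system, "A", "B", n=20, cutoff=8.0, seed=1)
        total, _ = rset.evaluate(contact_system)
        assert total == 0.0
        assert len(rset) == 20

    def test_same_seed_reproduces_sample(self, contact_system):
        r1 = sample_contact_restraints(contact_system, "A", "B", n=15, cutoff=8.0, seed=9)
        r2 = sample_contact_restraints(contact_system, "A", "B", n=15, cutoff=8.0, seed=9)
        assert r1.to_tsv() == r2.to_tsv()

    def test_insufficient_pairs_reports_count(self, contact_system):
        with pytest.raises(ValueError, match="cross-chain pairs"):
            sample_contact_restraints(contact_system, "A", "B", n=10_000, cutoff=8.0)


class TestSerialization:
    def test_tsv_round_trip_is_lossless(self):
        rset = RestraintSet(stage="mixed")
        rset.add(DistanceRestraint(BeadId("A", 1), BeadId("B", 2), 4.25, 0.4, 0.6, 2.0))
        rset.add(HBondRestraint(BeadId("A", 3), BeadId("A", 6), 5.1, 0.3, 0.3))
        rset.add(AmbiguousRestraint((BeadId("A", 73),), (BeadId("B", 119), BeadId("B", 142)), 5.0))
        rset.add(TorsionRestraint(tuple(BeadId("A", i) for i in (1, 2, 3, 4)), 50.0, 10.0))
        rset.add(PlanarityRestraint(tuple(BeadId("C", i) for i in (1, 2, 3, 4)), 1.9))
        text = rset.to_tsv()
        back = RestraintSet.from_tsv(text)
        assert back.to_tsv() == text
        assert len(back) == len(rset)
        assert isinstance(back.distances[1], HBondRestraint)

    def test_header_required(self):
        with pytest.raises(ValueError, match="header"):
            RestraintSet.from_tsv("distance\tA:1\tB:2\t4.0\t0.5\t0.5\t1.0\tx\n")
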