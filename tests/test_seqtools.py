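"""Motif scanning, palindrome/spacing analysis and helical-wheel geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soxdimer.seqtools import (
    DuplexProbe,
    FaceReport,
    MotifPattern,
    ProteinRegion,
    SiteHit,
    WheelProjection,
    check_palindrome,
    hydrophobic_face,
    predict_phenotype,
    reverse_complement,
    scan_motif,
    site_spacing,
)

IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def brute_force_scan(top: str, pattern: str, max_mm: int):
    """Independent oracle: enumerate every window on both strands."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    bottom_of = lambda s: "".join(comp[c] for c in reversed(s))
    hits = []
    L = len(pattern)
    for start in range(len(top) - L + 1):
        window = top[start : start + L]
        mm_plus = sum(b not in IUPAC_ORACLE[p] for b, p in zip(window, pattern))
        if mm_plus <= max_mm:
            hits.append((start, "+"))
        mm_minus = sum(
            b not in IUPAC_ORACLE[p] for b, p in zip(bottom_of(window), pattern)
        )
        if mm_minus <= max_mm:
            hits.append((start, "-"))
    return sorted(hits)


class TestScanMotif:
    def test_cc36_has_two_inverted_canonical_sites(self, cc36):
        hits = scan_motif(cc36, MotifPattern("CACAAAG"))
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}

    def test_s9wt_has_one_consensus_site(self, s9wt):
        hits = scan_motif(s9wt, MotifPattern("AACAATG"))
        assert len(hits) == 1
        assert hits[0].strand == "+"

    def test_absent_motif_yields_no_hits(self):
        probe = DuplexProbe("polyA", "A" * 20)
        assert scan_motif(probe, MotifPattern("CACAAAG")) == []

    def test_degenerate_consensus_needs_one_mismatch_on_cc36(self, cc36):
        # the CC36 sites carry C, not A/T, at the first consensus position
        assert scan_motif(cc36, MotifPattern("WWCAAWG", 0)) == []
        hits = scan_motif(cc36, MotifPattern("WWCAAWG", 1))
        assert len(hits) == 2

    def test_motif_longer_than_probe_is_empty_not_error(self):
        probe = DuplexProbe("tiny", "ACGT")
        assert scan_motif(probe, MotifPattern("ACGTACGT")) == []

    def test_invalid_iupac_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifPattern("ACGX")

    @given(
        top=st.text(alphabet="ACGT", min_size=8, max_size=50),
        pattern=st.text(alphabet="ACGTWSRYN", min_size=2, max_size=7),
        max_mm=st.integers(min_value=0, max_value=2),
    )
    def test_agrees_with_brute_force_oracle(self, top, pattern, max_mm):
        probe = DuplexProbe("rand", top)
        got = [(h.start, h.strand) for h in scan_motif(probe, MotifPattern(pattern, max_mm))]
        assert sorted(got) == brute_force_scan(top, pattern, max_mm)

    @given(half=st.text(alphabet="ACGT", min_size=6, max_size=20))
    def test_palindromic_probe_gives_strand_symmetric_hits(self, half):
        top = half + reverse_complement(half)
        probe = DuplexProbe("pal", top)
        motif = MotifPattern("CAAAG", 1)
        hits = scan_motif(probe, motif)
        starts_plus = {h.start for h in hits if h.strand == "+"}
        starts_minus = {h.start for h in hits if h.strand == "-"}
        mirrored = {len(top) - s - len(motif) for s in starts_plus}
        assert mirrored == starts_minus


class TestPalindromeAndSpacing:
    def test_cc36_is_a_36bp_palindrome(self, cc36):
        assert len(cc36) == 36
        assert check_palindrome(cc36)

    def test_s9wt_is_not_palindromic(self, s9wt):
        assert not check_palindrome(s9wt)

    def test_two_bp_palindrome(self):
        assert check_palindrome(DuplexProbe("at", "AT"))

    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=30))
    def test_palindromy_invariant_under_reverse_complement(self, seq):
        a = DuplexProbe("x", seq)
        b = DuplexProbe("y", reverse_complement(seq))
        assert check_palindrome(a) == check_palindrome(b)

    def test_cc36_sites_are_spaced_four_bp(self, cc36):
        hits = scan_motif(cc36, MotifPattern("CACAAAG"))
        assert site_spacing(hits) == 4
        assert site_spacing(list(reversed(hits))) == 4

    def test_abutting_footprints_have_zero_spacing(self):
        hits = [SiteHit(0, 7, "+", "x" * 7), SiteHit(7, 7, "-", "y" * 7)]
        assert site_spacing(hits) == 0

    def test_explicit_gap(self):
        hits = [SiteHit(0, 7, "+", "x" * 7), SiteHit(11, 7, "-", "y" * 7)]
        assert site_spacing(hits) == 4

    def test_same_strand_hits_rejected(self):
        hits = [SiteHit(0, 7, "+", "x" * 7), SiteHit(11, 7, "+", "y" * 7)]
        with pytest.raises(ValueError, match="opposite strands"):
            site_spacing(hits)

    def test_wrong_hit_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            site_spacing([SiteHit(0, 7, "+", "x" * 7)])


class TestHelicalWheel:
    def test_dimerization_region_face(self, dimer_region):
        report = hydrophobic_face(dimer_region)
        assert set(report.residues) == {73, 76, 77, 80, 81, 84}
        assert report.arc_start == pytest.approx(40.0)
        assert report.arc_span == pytest.approx(140.0)
        assert report.clean_separation

    def test_all_hydrophobic_region_has_no_separation(self):
        region = ProteinRegion("L" * 10, start=1)
        report = hydrophobic_face(region)
        assert len(report.residues) == 10
        assert not report.clean_separation

    def test_alternating_pattern_is_not_amphipathic(self):
        region = ProteinRegion("LS" * 6, start=1)
        report = hydrophobic_face(region)
        assert not report.clean_separation

    def test_no_hydrophobic_residues_flagged(self):
        region = ProteinRegion("SSSSQQQQ", start=1)
        report = hydrophobic_face(region)
        assert report.residues == ()
        assert report.arc_span is None
        assert not report.clean_separation

    def test_wheel_angles_invariant_to_renumbering(self, dimer_region):
        shifted = ProteinRegion(dimer_region.sequence, start=200)
        wheel = WheelProjection()
        a1 = list(wheel.angles(dimer_region).values())
        a2 = list(wheel.angles(shifted).values())
        assert a1 == a2
        r1 = hydrophobic_face(dimer_region)
        r2 = hydrophobic_face(shifted)
        assert r1.arc_span == r2.arc_span
        assert r1.clean_separation == r2.clean_separation

    def test_short_region_rejected(self):
        with pytest.raises(ValueError, match="short"):
            hydrophobic_face(ProteinRegion("LSA", start=1))


class TestPhenotypePrediction:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (77, "loss"),  # V77E, hydrophobic face
            (73, "loss"),
            (84, "loss"),
            (119, "loss"),  # A119E, HMG platform
            (142, "loss"),  # L142Q
            (78, "retained"),  # S78A assayed neutral
            (79, "retained"),
            (118, "retained"),  # A118E retains dimerization
            (145, "retained"),  # L145E
            (100, "unknown"),
        ],
    )
    def test_positional_calls(self, position, expected):
        assert predict_phenotype(position) == expected
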