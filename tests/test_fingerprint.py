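"""Motif scanning, spacing fingerprints, and signature matching.

The key guarantees checked here: fingerprints are strand-symmetric
(because all motifs are reverse-complement palindromes), and signature
matching is equivalent to a brute-force string suffix–prefix matcher on
pairs constructed with planted exact overlaps.
"""

import numpy as np
import pytest

from snassembly.fingerprint import (
    DEFAULT_MOTIFS,
    MotifConfigError,
    MotifFingerprint,
    MotifSet,
    fingerprint,
    match_signatures,
    scan_motif,
)
from snassembly.seqio import Contig, reverse_complement


def fp(gaps, pos0=0, length=None, contig_id="x", motif="CATG"):
    """Build a fingerprint directly from a gap list (for matcher unit tests)."""
    positions = [pos0]
    for g in gaps:
        positions.append(positions[-1] + g)
    length = length or positions[-1] + len(motif) + 50
    return MotifFingerprint(contig_id, motif, tuple(positions), tuple(gaps), length)


class TestMotifSet:
    def test_default_motifs_are_their_own_reverse_complement(self):
        for m in MotifSet().motifs:
            assert reverse_complement(m) == m
        assert MotifSet().motifs == DEFAULT_MOTIFS

    def test_non_palindromic_motif_rejected(self):
        with pytest.raises(MotifConfigError):
            MotifSet(("CATG", "AAA"))
        with pytest.raises(MotifConfigError):
            MotifSet(("G",))


class TestScanMotif:
    @pytest.mark.parametrize("seq,motif,expected", [
        ("CATGCATG", "CATG", [0, 4]),
        ("TATATA", "TATA", [0, 2]),   # overlapping occurrences are reported
        ("CANG", "CATG", []),         # N never matches
        ("GCGCGC", "GC", [0, 2, 4]),
    ])
    def test_all_occurrences(self, seq, motif, expected):
        assert scan_motif(seq, motif) == expected


class TestFingerprint:
    def test_positions_and_gaps(self):
        c = Contig("c", "CATGAACATGCATG", frozenset({"n"}))
        f = MotifFingerprint.of(c, "CATG")
        assert f.positions == (0, 6, 10)
        assert f.gaps == (6, 4)

    def test_fewer_than_two_occurrences_gives_empty_gaps(self):
        c = Contig("c", "CATGAAAA", frozenset({"n"}))
        assert MotifFingerprint.of(c, "CATG").gaps == ()
        assert MotifFingerprint.of(c, "CTAG").positions == ()

    def test_reverse_complement_reflects_positions_and_reverses_gaps(self):
        rng = np.random.default_rng(42)
        for motif in DEFAULT_MOTIFS:
            s = "".join(rng.choice(list("ACGT"), 400))
            c = Contig("c", s, frozenset({"n"}))
            rc = Contig("r", reverse_complement(s), frozenset({"n"}))
            f, g = MotifFingerprint.of(c, motif), MotifFingerprint.of(rc, motif)
            L, m = len(s), len(motif)
            assert g.positions == tuple(L - m - p for p in reversed(f.positions))
            assert g.gaps == tuple(reversed(f.gaps))
            assert f.reversed().positions == g.positions
            assert f.reversed().gaps == g.gaps

    def test_one_fingerprint_per_motif(self):
        c = Contig("c", "CATGCATGGC", frozenset({"n"}))
        fps = fingerprint(c)
        assert [f.motif for f in fps] == list(DEFAULT_MOTIFS)


class TestMatchSignatures:
    def test_single_suffix_prefix_run(self):
        a, b = fp([7, 3, 9, 4]), fp([9, 4, 11], contig_id="y")
        out = match_signatures(a, b, min_run=2)
        assert len(out) == 1
        assert out[0].run_length == 2

    def test_periodic_signature_yields_all_alignments(self):
        a = fp([5, 5, 5], pos0=10, length=40)
        b = fp([5, 5, 5], contig_id="y", length=40)
        runs = [m.run_length for m in match_signatures(a, b, min_run=2)]
        assert runs == [3, 2]  # sorted run_length desc

    def test_min_run_larger_than_lists(self):
        assert match_signatures(fp([5, 5]), fp([5, 5], contig_id="y"), min_run=5) == []

    def test_gap_tolerance_admits_near_matches(self):
        a, b = fp([10, 20, 30]), fp([11, 19, 31, 8], contig_id="y")
        assert match_signatures(a, b, min_run=3, gap_tolerance=0) == []
        assert len(match_signatures(a, b, min_run=3, gap_tolerance=1)) == 1

    def test_mismatched_motifs_rejected(self):
        with pytest.raises(ValueError):
            match_signatures(fp([5]), fp([5], motif="GC"))


def _planted_pair(rng, overlap_len):
    """A = X·O, B = O·Y with an exact shared overlap O."""
    mk = lambda n: "".join(rng.choice(list("ACGT"), n, p=[0.36, 0.14, 0.14, 0.36]))
    x, o, y = mk(rng.integers(300, 1500)), mk(overlap_len), mk(rng.integers(300, 1500))
    return x + o, o + y, len(x), len(o)


def _brute_force_overlap(a, b):
    """Longest suffix of a that equals a prefix of b (string oracle)."""
    for n in range(min(len(a), len(b)) - 1, 0, -1):
        if a[-n:] == b[:n]:
            return n
    return 0


class TestOracleEquivalence:
    def test_signature_matching_finds_planted_exact_overlaps(self):
        """Whenever the true overlap holds >= min_run+1 occurrences of a
        motif, a signature match must imply an overlap at least as long as
        the truth minus motif-length edge effects."""
        rng = np.random.default_rng(7)
        min_run = 4
        n_checked = 0
        for _ in range(60):
            seq_a, seq_b, true_off, true_ovl = _planted_pair(rng, rng.integers(200, 2000))
            truth = _brute_force_overlap(seq_a, seq_b)
            assert truth >= true_ovl  # oracle sanity
            ca = Contig("a", seq_a, frozenset({"n"}))
            cb = Contig("b", seq_b, frozenset({"n"}))
            for motif in DEFAULT_MOTIFS:
                occ_in_overlap = [p for p in scan_motif(seq_a, motif)
                                  if p >= true_off and p + len(motif) <= len(seq_a)]
                if len(occ_in_overlap) < min_run + 1:
                    continue
                fa = MotifFingerprint.of(ca, motif)
                fb = MotifFingerprint.of(cb, motif)
                matches = match_signatures(fa, fb, min_run=min_run)
                assert matches, f"no match for motif {motif}"
                best = max(m.implied_overlap_bp for m in matches)
                assert best >= truth - (len(motif) - 1)
                n_checked += 1
        assert n_checked > 50  # the construction actually exercised the matcher

    def test_strand_symmetry_of_matching(self):
        """Matching A against reversed-B fingerprints finds exactly what the
        forward matcher finds between A and reverse_complement(B)."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq_a, seq_b, _, _ = _planted_pair(rng, rng.integers(200, 600))
            ca = Contig("a", seq_a, frozenset({"n"}))
            cb = Contig("b", seq_b, frozenset({"n"}))
            cbrc = Contig("b", reverse_complement(seq_b), frozenset({"n"}))
            for motif in ("GC", "TATA", "CATG"):
                fa = MotifFingerprint.of(ca, motif)
                via_reversed = match_signatures(fa, MotifFingerprint.of(cb, motif).reversed())
                via_rc_string = match_signatures(fa, MotifFingerprint.of(cbrc, motif))
                assert [(m.run_length, m.offset) for m in via_reversed] == \
                       [(m.run_length, m.offset) for m in via_rc_string]
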