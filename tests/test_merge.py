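"""Consensus merging: verification, mutual-maximal selection, full recovery."""

import numpy as np
import pytest

from snassembly.fingerprint import MotifFingerprint, MotifSet, match_signatures
from snassembly.merge import (
    VerifiedOverlap,
    consensus_merge,
    length_filter,
    merge_pair,
    remove_contained,
    replay_log,
    select_mutual_maximal,
    verify_overlap,
)
from snassembly.seqio import Contig, reverse_complement

AT_RICH = [0.36, 0.14, 0.14, 0.36]  # A, C, G, T


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n, p=AT_RICH))


def contig(id_, seq, nucleus=None):
    return Contig(id_, seq, frozenset({nucleus or id_}))


class TestLengthFilter:
    def test_smaller_than_is_strict(self):
        contigs = [contig(f"c{n}", "A" * n) for n in (499, 500, 501)]
        assert [len(c) for c in length_filter(contigs, 500)] == [500, 501]

    def test_zero_is_identity(self):
        contigs = [contig("c", "ACGT")]
        assert length_filter(contigs, 0) == contigs

    def test_all_filtered_yields_empty_merge_without_error(self):
        contigs = [contig("c", "ACGT")]
        assembly, log = consensus_merge([contigs], min_len=2000)
        assert assembly == [] and log.n_merges == 0


def _verified_match(seq_a, seq_b, motif="GC", min_run=4):
    ca, cb = contig("a", seq_a), contig("b", seq_b)
    fa = MotifFingerprint.of(ca, motif)
    fb = MotifFingerprint.of(cb, motif)
    matches = match_signatures(fa, fb, min_run=min_run)
    assert matches
    return ca, cb, matches[0]


class TestVerifyOverlap:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.x = random_dna(rng, 700)
        self.o = random_dna(rng, 300)
        self.y = random_dna(rng, 500)

    def test_exact_overlap_retained_with_identity_one(self):
        ca, cb, m = _verified_match(self.x + self.o, self.o + self.y)
        ov = verify_overlap(ca, cb, m)
        assert ov is not None
        assert ov.overlap_bp == 300 and ov.identity == 1.0

    def test_seven_substitutions_rejected_at_default_threshold(self):
        o_mut = list(self.o)
        for i in range(0, 7 * 40, 40):  # avoid touching GC motif spacing? no need:
            pass
        # place substitutions at fixed non-motif-critical sites
        rng = np.random.default_rng(9)
        sites = rng.choice(300, size=7, replace=False)
        for i in sites:
            o_mut[i] = {"A": "T", "T": "A", "C": "A", "G": "T"}[o_mut[i]]
        ca = contig("a", self.x + self.o)
        cb = contig("b", "".join(o_mut) + self.y)
        fa = MotifFingerprint.of(ca, "GC")
        fb = MotifFingerprint.of(cb, "GC")
        matches = match_signatures(fa, fb, min_run=4, gap_tolerance=0)
        if not matches:  # a substitution hit a GC site; widen via another motif
            pytest.skip("substitutions destroyed the signature (construction fluke)")
        ov = verify_overlap(ca, cb, matches[0])
        assert ov is None  # 293/300 = 0.9767 < 0.98

    def test_short_overlap_rejected_regardless_of_identity(self):
        rng = np.random.default_rng(5)
        x, y = random_dna(rng, 400), random_dna(rng, 400)
        o = list(random_dna(rng, 150))
        for i in (10, 50, 90, 130):  # guarantee a GC spacing signature
            o[i : i + 2] = "GC"
        o = "".join(o)
        ca, cb, m = _verified_match(x + o, o + y, min_run=2)
        assert verify_overlap(ca, cb, m) is None


def vo(a, b, bp, ident=1.0, a_strand="+", b_strand="+", offset=100):
    return VerifiedOverlap(a, b, a_strand, b_strand, offset, bp, ident)


class TestSelectMutualMaximal:
    def test_one_sided_preference_is_not_selected(self):
        # A<->B mutual best at 300 bp; A<->C at 250 bp is one-sided
        sel = select_mutual_maximal([vo("A", "B", 300), vo("A", "C", 250)])
        assert [(o.contig_a, o.contig_b) for o in sel] == [("A", "B")]

    def test_non_mutual_chain_leaves_contig_unpaired(self):
        # A's best is B, but B's best (same left end) is C
        sel = select_mutual_maximal([vo("A", "B", 300), vo("C", "B", 400, offset=50)])
        assert [(o.contig_a, o.contig_b) for o in sel] == [("C", "B")]
        assert not any("A" in (o.contig_a, o.contig_b) for o in sel)

    def test_tie_breaks_to_smaller_partner_id(self):
        sel = select_mutual_maximal([vo("A", "C", 300), vo("A", "B", 300)])
        assert [(o.contig_a, o.contig_b) for o in sel] == [("A", "B")]

    def test_selected_pairs_are_vertex_disjoint(self):
        # B could merge left with A and right with C; one merge per pass
        left = vo("A", "B", 300)
        right = vo("B", "C", 250)
        sel = select_mutual_maximal([left, right])
        used = [c for o in sel for c in (o.contig_a, o.contig_b)]
        assert len(used) == len(set(used))


class TestMergePair:
    def test_merged_length_arithmetic(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 1500)
        a, b = contig("a", ref[:1000]), contig("b", ref[700:])
        ov = vo("a", "b", 300, offset=700)
        merged = merge_pair(a, b, ov)
        assert len(merged) == 1000 + 800 - 300
        assert merged.sequence == ref  # exact overlap reproduces the reference
        assert merged.source_nuclei == {"a", "b"}
        assert merged.merge_depth == 1

    def test_mismatch_takes_base_from_longer_contig(self):
        rng = np.random.default_rng(2)
        ref = random_dna(rng, 1200)
        seq_b = list(ref[700:])
        seq_b[10] = "A" if seq_b[10] != "A" else "C"  # 1 mismatch in overlap
        a, b = contig("a", ref[:1000]), contig("b", "".join(seq_b))
        merged = merge_pair(a, b, vo("a", "b", 300, ident=299 / 300, offset=700))
        assert merged.sequence[710] == ref[710]  # longer contig (a) wins


def tiling_sets(rng, ref, n_pieces=10, min_ovl=300, max_ovl=500, n_sets=2):
    """Cut a reference into overlapping pieces distributed over contig sets."""
    bounds = np.sort(rng.choice(np.arange(2000, len(ref) - 2000, 100),
                                size=n_pieces - 1, replace=False))
    pieces = []
    starts = [0] + list(bounds)
    ends = list(bounds) + [len(ref)]
    for i, (s, e) in enumerate(zip(starts, ends)):
        ext = int(rng.integers(min_ovl, max_ovl))
        pieces.append(Contig(f"p{i:02d}", ref[max(0, s - ext): e],
                             frozenset({f"n{i % n_sets}"})))
    sets = [[] for _ in range(n_sets)]
    for i, p in enumerate(pieces):
        sets[i % n_sets].append(p)
    return sets


class TestConsensusMerge:
    def test_tiled_reference_recovers_exactly(self):
        rng = np.random.default_rng(17)
        ref = random_dna(rng, 50_000)
        assembly, log = consensus_merge(tiling_sets(rng, ref))
        assert len(assembly) == 1
        assert assembly[0].sequence in (ref, reverse_complement(ref))
        assert log.n_merges == 9

    def test_identical_contigs_collapse_by_containment(self):
        rng = np.random.default_rng(19)
        s = random_dna(rng, 3000)
        assembly, log = consensus_merge([[contig("a", s)], [contig("b", s, "nb")]])
        assert len(assembly) == 1 and log.n_merges == 0

    def test_no_shared_motifs_means_no_merges(self):
        a = [contig("a", "A" * 500)]
        b = [contig("b", "A" * 400 + "T" * 100, "nb")]
        assembly, _ = consensus_merge([a, b])
        assert sorted(c.id for c in assembly) == ["a", "b"]

    def test_conservation_of_sequence(self, contig_sets24, consensus24):
        assembly, log = consensus24
        total_in = sum(len(c) for cs in contig_sets24 for c in cs)
        assert sum(len(c) for c in assembly) <= total_in

    def test_idempotence(self, consensus24):
        assembly, _ = consensus24
        again, log = consensus_merge([assembly])
        assert log.n_merges == 0
        assert [c.sequence for c in again] == [c.sequence for c in assembly]

    def test_order_robustness(self):
        rng = np.random.default_rng(23)
        ref = random_dna(rng, 30_000)
        sets = tiling_sets(rng, ref, n_pieces=6)
        a1, _ = consensus_merge(sets)
        shuffled = [list(reversed(s)) for s in reversed(sets)]
        a2, _ = consensus_merge(shuffled)
        assert sorted(c.sequence for c in a1) == sorted(c.sequence for c in a2)

    def test_replay_log_reproduces_assembly(self, contig_sets24, consensus24):
        assembly, log = consensus24
        replayed = replay_log(contig_sets24, log)
        assert [c.sequence for c in replayed] == [c.sequence for c in assembly]

    def test_repeat_copies_do_not_cause_chimeric_joins(self, scenario_small):
        """With a 3 kb two-copy repeat planted, every consensus contig must
        still be a clean substring of the reference (no flank swap)."""
        import edlib
        sets = scenario_small.contig_sets()
        assembly, _ = consensus_merge(sets)
        ref = scenario_small.reference.sequence
        for c in assembly:
            hit = min(
                edlib.align(c.sequence, ref, mode="HW", task="distance")["editDistance"],
                edlib.align(reverse_complement(c.sequence), ref, mode="HW",
                            task="distance")["editDistance"],
            )
            assert hit <= 0.02 * len(c), f"chimeric contig {c.id} ({len(c)} bp)"


class TestRemoveContained:
    def test_exact_and_reverse_complement_containment(self):
        rng = np.random.default_rng(29)
        host = random_dna(rng, 5000)
        inner = host[1000:2500]
        kept, removed = remove_contained(
            [contig("h", host), contig("i", inner),
             contig("r", reverse_complement(inner), "nr")],
            MotifSet())
        assert [c.id for c in kept] == ["h"]
        assert {r[0] for r in removed} == {"i", "r"}

    def test_non_contained_overlapping_contigs_survive(self):
        rng = np.random.default_rng(31)
        ref = random_dna(rng, 6000)
        kept, removed = remove_contained(
            [contig("a", ref[:4000]), contig("b", ref[2000:], "nb")], MotifSet())
        assert len(kept) == 2 and not removed
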