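"""Motif-spacing fingerprints and candidate suffix–prefix overlap detection.

The consensus merger does not align contigs base-by-base to find overlap
candidates.  Instead, each contig is summarised per motif by the ordered
list of distances (gaps) between consecutive occurrences of that motif —
its spacing fingerprint.  Two contigs that truly overlap share a run of
identical gaps: a suffix of the left contig's gap list equals a prefix of
the right contig's.  Because every motif in the default set is its own
reverse complement, the fingerprint of the reverse-complement strand is
simply the reversed gap list, so candidate search is strand-symmetric.

A signature match is a CANDIDATE only; spacing identity does not imply
sequence identity, and base-level verification happens in the merge module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import Contig, reverse_complement

#: Motifs used by the merge stage, in scan order.  All are reverse-complement
#: palindromes, which makes spacing fingerprints strand-invariant.
DEFAULT_MOTIFS = ("CATG", "CTAG", "GTAC", "GATC", "TATA", "ATAT", "GC")

DEFAULT_MIN_RUN = 4
DEFAULT_GAP_TOLERANCE = 0

FORWARD = "forward"
REVERSE = "reverse"


class MotifConfigError(ValueError):
    """A configured motif would break strand symmetry."""


@dataclass(frozen=True)
class MotifSet:
    motifs: tuple[str, ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) < 2:
                raise MotifConfigError(f"motif {m!r}: length must be >= 2")
            if reverse_complement(m) != m:
                raise MotifConfigError(
                    f"motif {m!r} is not its own reverse complement; "
                    "spacing fingerprints would not be strand-invariant"
                )

    def __iter__(self):
        return iter(self.motifs)


@dataclass(frozen=True)
class MotifFingerprint:
    """Occurrence positions and inter-occurrence gaps of one motif in one contig."""

    contig_id: str
    motif: str
    positions: tuple[int, ...]
    gaps: tuple[int, ...]
    length: int  # contig length, needed for overlap arithmetic and strand flips

    @classmethod
    def of(cls, contig: Contig, motif: str) -> "MotifFingerprint":
        positions = tuple(scan_motif(contig.sequence, motif))
        gaps = tuple(positions[i + 1] - positions[i] for i in range(len(positions) - 1))
        return cls(contig.id, motif, positions, gaps, len(contig.sequence))

    def reversed(self) -> "MotifFingerprint":
        """Fingerprint of the reverse-complement strand.

        Valid because motifs are reverse-complement palindromes: an
        occurrence at p maps to L - m - p, so positions reflect and the gap
        list reverses.
        """
        m = len(self.motif)
        positions = tuple(self.length - m - p for p in reversed(self.positions))
        return MotifFingerprint(self.contig_id, self.motif, positions,
                                tuple(reversed(self.gaps)), self.length)


@dataclass(frozen=True)
class SignatureMatch:
    """Candidate suffix(A)–prefix(B) overlap implied by a shared gap run.

    ``offset`` is the 0-based position in A (forward strand) where B's
    matched region begins, so the implied overlap spans A[offset:].
    """

    contig_a: str
    contig_b: str
    orientation: str  # FORWARD or REVERSE: orientation of B relative to A
    run_length: int
    offset: int
    implied_overlap_bp: int


def scan_motif(sequence: str, motif: str) -> list[int]:
    """All start positions of exact motif occurrences, overlaps included.

    N never matches any motif base (str.find on the cleaned alphabet already
    guarantees this: motifs contain no N).
    """
    positions = []
    i = sequence.find(motif)
    while i != -1:
        positions.append(i)
        i = sequence.find(motif, i + 1)
    return positions


def fingerprint(contig: Contig, motif_set: MotifSet | None = None) -> list[MotifFingerprint]:
    motif_set = motif_set or MotifSet()
    return [MotifFingerprint.of(contig, m) for m in motif_set]


def _gaps_match(a: Sequence[int], b: Sequence[int], tol: int) -> bool:
    return all(abs(x - y) <= tol for x, y in zip(a, b))


def match_signatures(
    fp_a: MotifFingerprint,
    fp_b: MotifFingerprint,
    min_run: int = DEFAULT_MIN_RUN,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    orientation: str = FORWARD,
) -> list[SignatureMatch]:
    """All suffix(A)/prefix(B) gap-run alignments of length >= min_run.

    This is the brute-force definition of a candidate overlap: for every
    suffix start i of A's gap list, the entire suffix ``gaps_a[i:]`` must
    equal ``gaps_b[:len(gaps_a)-i]`` element-wise within ±gap_tolerance.
    Alignments whose implied overlap would not fit inside both contigs are
    dropped.  Output is sorted by (run_length desc, offset asc).
    """
    if fp_a.motif != fp_b.motif:
        raise ValueError("fingerprints are for different motifs")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    gaps_a, gaps_b = fp_a.gaps, fp_b.gaps
    out = []
    for i in range(0, len(gaps_a) - min_run + 1):
        run = len(gaps_a) - i
        if run > len(gaps_b):
            continue
        if not _gaps_match(gaps_a[i:], gaps_b[:run], gap_tolerance):
            continue
        offset = fp_a.positions[i] - fp_b.positions[0]
        implied = fp_a.length - offset
        if offset < 0 or implied > min(fp_a.length, fp_b.length):
            continue
        out.append(SignatureMatch(fp_a.contig_id, fp_b.contig_id, orientation,
                                  run, offset, implied))
    out.sort(key=lambda m: (-m.run_length, m.offset))
    return out


# ---------------------------------------------------------------------------
# Indexed candidate generation over a contig pool
# ---------------------------------------------------------------------------

@dataclass
class FingerprintIndex:
    """Shingle index over one motif's fingerprints for a contig pool.

    For exact matching (gap_tolerance 0) a run of >= min_run shared gaps
    necessarily begins with B's length-min_run gap prefix appearing as a
    window in A, so hashing prefix shingles finds every candidate the
    brute-force all-pairs scan would.  With a nonzero tolerance the index
    is bypassed and all pairs are matched directly.
    """

    min_run: int = DEFAULT_MIN_RUN
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE
    # prefix shingle -> list of (fingerprint, orientation) whose gap list starts with it
    _prefixes: dict[tuple[int, ...], list[tuple[MotifFingerprint, str]]] = field(
        default_factory=dict)
    _all: list[tuple[MotifFingerprint, str]] = field(default_factory=list)

    def add(self, fp: MotifFingerprint) -> None:
        for oriented, orient in ((fp, FORWARD), (fp.reversed(), REVERSE)):
            self._all.append((oriented, orient))
            if len(oriented.gaps) >= self.min_run:
                key = oriented.gaps[: self.min_run]
                self._prefixes.setdefault(key, []).append((oriented, orient))

    def candidates(self, fp_a: MotifFingerprint) -> list[SignatureMatch]:
        """Candidate overlaps extending A's right (forward-strand) end."""
        matches: list[SignatureMatch] = []
        seen: set[tuple[str, str]] = set()
        gaps_a = fp_a.gaps
        if self.gap_tolerance == 0:
            pool: list[tuple[MotifFingerprint, str]] = []
            for i in range(0, len(gaps_a) - self.min_run + 1):
                for fp_b, orient in self._prefixes.get(gaps_a[i : i + self.min_run], ()):
                    if fp_b.contig_id != fp_a.contig_id and (fp_b.contig_id, orient) not in seen:
                        seen.add((fp_b.contig_id, orient))
                        pool.append((fp_b, orient))
        else:
            pool = [(fp_b, orient) for fp_b, orient in self._all
                    if fp_b.contig_id != fp_a.contig_id]
        for fp_b, orient in pool:
            matches.extend(match_signatures(fp_a, fp_b, self.min_run,
                                            self.gap_tolerance, orientation=orient))
        matches.sort(key=lambda m: (-m.run_length, m.offset, m.contig_b, m.orientation))
        return matches


def export_fingerprints_tsv(fps: Iterable[MotifFingerprint], path) -> None:
    """Debug dump: contig_id, motif, comma-joined positions."""
    with open(path, "w") as fh:
        fh.write("contig_id\tmotif\tpositions\n")
        for fp in fps:
            fh.write(f"{fp.contig_id}\t{fp.motif}\t{','.join(map(str, fp.positions))}\n")
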