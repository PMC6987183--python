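"""Digital normalization of paired reads to a target average depth.

MDA amplification leaves per-locus read depth wildly uneven; assemblers
behave better when the depth distribution is flattened.  Normalization here
is a single streaming pass: each pair's depth is estimated as the median
count of its canonical k-mers in an index built from the pairs kept so
far, and only kept pairs feed the index.  The keep decision is
deliberately conservative — a pair is kept only while *none* of its
k-mers has reached the target count.  A median keep-rule equilibrates
above the target wherever coverage is positionally heterogeneous (the
upper half of a pair's counts is ignored), whereas the saturation rule
used here caps every k-mer count in the kept set at the target by
construction, so re-estimating kept pairs against the kept-only index
stays at or below the target.  The kept set is therefore always a subsequence of
the input, and pairs are the atomic unit — mates are kept or dropped
together so downstream assemblers see intact pairing.

Running the pass on each nucleus separately or on the concatenation of all
nuclei are the two workflow topologies (per-nucleus vs pooled
normalization); both use this one operation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .seqio import NucleusReadSet, ReadPair, reverse_complement

DEFAULT_K = 31
DEFAULT_TARGET_DEPTH = 100


class DepthUndefinedError(ValueError):
    """A read pair yields no k-mers (reads shorter than k)."""


@dataclass
class KmerDepthIndex:
    """Exact canonical k-mer counts (canonical = min of k-mer and its rc)."""

    k: int = DEFAULT_K
    counts: Counter = field(default_factory=Counter)

    def canonical_kmers(self, sequence: str) -> list[str]:
        k = self.k
        out = []
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            rc = reverse_complement(kmer)
            out.append(kmer if kmer <= rc else rc)
        return out

    def add(self, sequence: str) -> None:
        self.counts.update(self.canonical_kmers(sequence))


@dataclass
class NormalizationReport:
    pairs_in: int = 0
    pairs_kept: int = 0
    pairs_skipped_short: int = 0
    depth_histogram: Counter = field(default_factory=Counter)

    @property
    def kept_fraction(self) -> float:
        return self.pairs_kept / self.pairs_in if self.pairs_in else 0.0

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"pairs_in\t{self.pairs_in}\n")
            fh.write(f"pairs_kept\t{self.pairs_kept}\n")
            fh.write(f"pairs_skipped_short\t{self.pairs_skipped_short}\n")
            for depth in sorted(self.depth_histogram):
                fh.write(f"depth_{depth}\t{self.depth_histogram[depth]}\n")
        return path


def median_kmer_depth(pair: ReadPair, index: KmerDepthIndex) -> int:
    """Median count over both mates' canonical k-mers (lower-middle median).

    Raises :class:`DepthUndefinedError` when neither mate yields a k-mer.
    """
    kmers = index.canonical_kmers(pair.seq1) + index.canonical_kmers(pair.seq2)
    if not kmers:
        raise DepthUndefinedError(f"pair {pair.id!r}: reads shorter than k={index.k}")
    depths = sorted(index.counts[km] for km in kmers)
    return depths[(len(depths) - 1) // 2]


def normalize_reads(
    read_set: NucleusReadSet,
    target_depth: int = DEFAULT_TARGET_DEPTH,
    k: int = DEFAULT_K,
) -> tuple[NucleusReadSet, NormalizationReport]:
    """One-pass k-mer-depth normalization of a read set.

    The reported depth estimate per pair is the median of its canonical
    k-mer counts; the keep decision saturates at the target: a pair is
    kept iff no k-mer it contains has reached ``target_depth`` yet.  Kept
    pairs (and only those) feed the index.  Too-short pairs are skipped
    (counted, not fatal).
    """
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    index = KmerDepthIndex(k=k)
    report = NormalizationReport()
    kept: list[ReadPair] = []
    for pair in read_set.reads:
        report.pairs_in += 1
        kmers = index.canonical_kmers(pair.seq1) + index.canonical_kmers(pair.seq2)
        if not kmers:
            report.pairs_skipped_short += 1
            continue
        counts = sorted(index.counts[km] for km in kmers)
        depth = counts[(len(counts) - 1) // 2]
        report.depth_histogram[depth] += 1
        if counts[-1] < target_depth:
            kept.append(pair)
            report.pairs_kept += 1
            index.add(pair.seq1)
            index.add(pair.seq2)
    out = NucleusReadSet(nucleus_id=read_set.nucleus_id, reads=kept,
                         read_length=read_set.read_length)
    return out, report


def pool_read_sets(read_sets: list[NucleusReadSet], pooled_id: str = "pooled"
                   ) -> NucleusReadSet:
    """Concatenate per-nucleus read sets in input order (pooled topology)."""
    if not read_sets:
        raise ValueError("no read sets to pool")
    lengths = {rs.read_length for rs in read_sets}
    if len(lengths) != 1:
        raise ValueError(f"read sets have differing read lengths: {sorted(lengths)}")
    reads = [p for rs in read_sets for p in rs.reads]
    return NucleusReadSet(nucleus_id=pooled_id, reads=reads,
                          read_length=read_sets[0].read_length)
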