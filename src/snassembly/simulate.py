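"""Synthetic references, MDA-biased per-nucleus coverage, reads and assemblies.

Whole-genome amplification of a single nucleus recovers only part of the
genome, with strong stochastic coverage bias; only the union over many
nuclei approaches completeness.  The simulator models this phenomenology
with two knobs: the reference is partitioned into exponentially sized
segments, each segment is covered by a given nucleus with probability
``mean_covered_fraction`` (Bernoulli dropout), and each maximal covered
interval receives a lognormal amplification gain.  The union coverage of
``n`` independent nuclei then follows the analytic curve ``1 - (1-c)^n``,
which is what the nuclei-saturation analysis probes.

References carry planted truth: single-copy marker genes (the stand-in
for a curated single-copy ortholog set) and optional repeat families.
Truth coordinates are 0-based half-open and exportable as BED, so every
downstream expectation can be recomputed independently of the pipeline.

All operations are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import Contig, NucleusReadSet, ReadPair, reverse_complement, write_bed

DEFAULT_GC_TARGET = 0.28  # AT-rich, as typical for AM fungal genomes
DEFAULT_COVERED_FRACTION = 0.4
DEFAULT_SEGMENT_SCALE = 20_000
DEFAULT_GAIN_SIGMA = 1.0

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat family to plant: n_copies of one length-bp element."""

    family_id: str
    length: int
    n_copies: int = 2
    copy_identity: float = 0.99  # per-copy identity to the family consensus


@dataclass
class ReferenceTruth:
    sequence: str
    markers: list[tuple[str, int, int]]
    repeats: list[tuple[str, list[tuple[int, int]]]]
    gc_target: float
    seed: int

    def __len__(self) -> int:
        return len(self.sequence)

    def marker_sequences(self) -> list[tuple[str, str]]:
        return [(mid, self.sequence[s:e]) for mid, s, e in self.markers]

    def markers_bed(self, path: str | Path, chrom: str = "ref") -> Path:
        return write_bed([(chrom, s, e, mid) for mid, s, e in self.markers], path)

    def repeats_bed(self, path: str | Path, chrom: str = "ref") -> Path:
        rows = [(chrom, s, e, f"{fam}_copy{i}")
                for fam, copies in self.repeats for i, (s, e) in enumerate(copies)]
        return write_bed(rows, path)


@dataclass
class NucleusProfile:
    nucleus_id: str
    covered_intervals: list[tuple[int, int]]
    gains: list[float]
    reference_length: int

    @property
    def covered_fraction(self) -> float:
        return sum(e - s for s, e in self.covered_intervals) / self.reference_length

    def intervals_bed(self, path: str | Path, chrom: str = "ref") -> Path:
        rows = [(chrom, s, e, f"{self.nucleus_id}_iv{i}")
                for i, (s, e) in enumerate(self.covered_intervals)]
        return write_bed(rows, path)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given per-base rate (always to a different base)."""
    if rate <= 0:
        return arr
    arr = arr.copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr


def _place_features(rng: np.random.Generator, length: int,
                    sizes: list[int], max_tries: int = 2000) -> list[int]:
    """Non-overlapping start positions for features of the given sizes."""
    if sum(sizes) > length:
        raise SimulationError(
            f"cannot pack {sum(sizes)} bp of features into a {length} bp reference")
    taken: list[tuple[int, int]] = []
    starts = []
    for size in sizes:
        for _ in range(max_tries):
            s = int(rng.integers(0, length - size + 1))
            if all(e2 <= s or s + size <= s2 for s2, e2 in taken):
                taken.append((s, s + size))
                starts.append(s)
                break
        else:
            raise SimulationError("feature placement failed; reference too crowded")
    return starts


def make_reference(
    length: int,
    gc_target: float = DEFAULT_GC_TARGET,
    n_markers: int = 0,
    marker_len: int = 1500,
    repeat_spec: Sequence[RepeatSpec] = (),
    seed: int = 0,
) -> ReferenceTruth:
    """Random reference with planted single-copy markers and repeat families.

    Markers are distinct random sequences written once each into the
    backbone; repeat copies are mutated replicas of one family consensus.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    backbone = _random_dna(rng, length, gc_target)

    sizes = [marker_len] * n_markers
    for spec in repeat_spec:
        if spec.n_copies < 2:
            raise SimulationError(f"repeat family {spec.family_id}: need >= 2 copies")
        sizes += [spec.length] * spec.n_copies
    starts = _place_features(rng, length, sizes)

    markers = []
    for i in range(n_markers):
        s = starts[i]
        backbone[s : s + marker_len] = _random_dna(rng, marker_len, gc_target)
        markers.append((f"marker{i:03d}", s, s + marker_len))

    repeats = []
    pos = n_markers
    for spec in repeat_spec:
        consensus = _random_dna(rng, spec.length, gc_target)
        copies = []
        for _ in range(spec.n_copies):
            s = starts[pos]
            pos += 1
            copy = _mutate(rng, consensus, 1.0 - spec.copy_identity)
            backbone[s : s + spec.length] = copy
            copies.append((s, s + spec.length))
        repeats.append((spec.family_id, copies))

    return ReferenceTruth(sequence=backbone.tobytes().decode(),
                          markers=markers, repeats=repeats,
                          gc_target=gc_target, seed=seed)


def simulate_nucleus(
    reference: ReferenceTruth,
    mean_covered_fraction: float = DEFAULT_COVERED_FRACTION,
    segment_scale: float = DEFAULT_SEGMENT_SCALE,
    gain_sigma: float = DEFAULT_GAIN_SIGMA,
    seed: int = 0,
    nucleus_id: str | None = None,
) -> NucleusProfile:
    """Segmental Bernoulli dropout with lognormal amplification gain.

    The reference is cut into segments with exponentially distributed
    lengths (mean ``segment_scale``); each segment is covered independently
    with probability ``mean_covered_fraction``; runs of covered segments
    are merged into maximal intervals, each with one lognormal gain.
    """
    if not 0 < mean_covered_fraction <= 1:
        raise SimulationError("mean_covered_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    L = len(reference)
    boundaries = [0]
    while boundaries[-1] < L:
        boundaries.append(boundaries[-1] + max(1, int(rng.exponential(segment_scale))))
    boundaries[-1] = L

    intervals: list[tuple[int, int]] = []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        if rng.random() < mean_covered_fraction:
            if intervals and intervals[-1][1] == s:
                intervals[-1] = (intervals[-1][0], e)
            else:
                intervals.append((s, e))
    gains = [float(rng.lognormal(0.0, gain_sigma)) for _ in intervals]
    return NucleusProfile(nucleus_id=nucleus_id or f"nucleus{seed:03d}",
                          covered_intervals=intervals, gains=gains,
                          reference_length=L)


def simulate_reads(
    reference: ReferenceTruth,
    profile: NucleusProfile,
    mean_depth: float = 50.0,
    read_len: int = 150,
    insert_mean: int = 350,
    insert_sd: int = 35,
    error_rate: float = 0.0,
    seed: int = 0,
) -> NucleusReadSet:
    """Paired reads from covered intervals, at rates proportional to gain.

    Inserts are fully inside a covered interval (amplified fragments do not
    cross dropout boundaries), so no read touches uncovered sequence.
    """
    if read_len > insert_mean:
        raise SimulationError("read_len must be <= insert_mean")
    rng = np.random.default_rng(seed)
    usable = [(iv, g) for iv, g in zip(profile.covered_intervals, profile.gains)
              if iv[1] - iv[0] >= read_len]
    if not usable:
        return NucleusReadSet(profile.nucleus_id, [], read_len)
    weights = np.array([g * (e - s) for (s, e), g in usable], dtype=float)
    weights /= weights.sum()
    covered_bp = sum(e - s for (s, e), _ in usable)
    n_pairs = max(1, int(round(covered_bp * mean_depth / (2 * read_len))))

    pairs = []
    for i in range(n_pairs):
        (s, e), _g = usable[int(rng.choice(len(usable), p=weights))]
        max_insert = min(e - s, int(rng.normal(insert_mean, insert_sd)))
        insert = max(read_len, max_insert)
        start = int(rng.integers(s, e - insert + 1))
        frag = np.frombuffer(reference.sequence[start : start + insert].encode(),
                             dtype=np.uint8)
        m1 = _mutate(rng, frag[:read_len], error_rate).tobytes().decode()
        m2 = reverse_complement(
            _mutate(rng, frag[-read_len:], error_rate).tobytes().decode())
        if rng.random() < 0.5:  # fragment sampled from the minus strand
            m1, m2 = m2, m1
        qual = "I" * read_len
        pairs.append(ReadPair(id=f"{profile.nucleus_id}_r{i:06d}",
                              seq1=m1, seq2=m2, qual1=qual, qual2=qual))
    return NucleusReadSet(profile.nucleus_id, pairs, read_len)


def mock_assemble(
    reference: ReferenceTruth,
    profile: NucleusProfile,
    min_contig_len: int = 0,
    break_prob: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Contig]:
    """Idealised per-nucleus assembly: covered intervals become contigs.

    Each covered interval is emitted as one contig, optionally broken at
    random points (``break_prob`` expected breaks per kb) and with per-base
    substitution errors.  Adjacent pieces share no overlap: a single
    nucleus's assembly is internally non-redundant, so all redundancy an
    assembly pool exhibits comes from *other* nuclei.  This is the built-in
    stand-in behind the pluggable assembler boundary.
    """
    rng = np.random.default_rng(seed)
    contigs = []
    i = 0
    for s, e in profile.covered_intervals:
        cuts = [s, e]
        if break_prob > 0:
            n_breaks = rng.poisson(break_prob * (e - s) / 1000.0)
            cuts += [int(rng.integers(s + 1, e)) for _ in range(int(n_breaks))]
            cuts = sorted(set(cuts))
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a < max(1, min_contig_len):
                continue
            arr = np.frombuffer(reference.sequence[a:b].encode(), dtype=np.uint8)
            seq = _mutate(rng, arr, error_rate).tobytes().decode()
            contigs.append(Contig(id=f"{profile.nucleus_id}_c{i:03d}", sequence=seq,
                                  source_nuclei=frozenset({profile.nucleus_id}),
                                  merge_depth=0))
            i += 1
    return contigs


# ---------------------------------------------------------------------------
# Canonical test scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A full simulated study: reference plus per-nucleus profiles."""

    reference: ReferenceTruth
    profiles: list[NucleusProfile]
    seed: int

    def contig_sets(self, break_prob: float = 0.0, error_rate: float = 0.0,
                    min_contig_len: int = 0) -> list[list[Contig]]:
        return [
            mock_assemble(self.reference, p, min_contig_len=min_contig_len,
                          break_prob=break_prob, error_rate=error_rate,
                          seed=self.seed + 1000 + i)
            for i, p in enumerate(self.profiles)
        ]

    def read_sets(self, mean_depth: float = 50.0, error_rate: float = 0.0,
                  read_len: int = 150) -> list[NucleusReadSet]:
        return [
            simulate_reads(self.reference, p, mean_depth=mean_depth,
                           read_len=read_len, error_rate=error_rate,
                           seed=self.seed + 2000 + i)
            for i, p in enumerate(self.profiles)
        ]


def make_scenario(
    seed: int,
    length: int = 200_000,
    n_nuclei: int = 24,
    covered_fraction: float = DEFAULT_COVERED_FRACTION,
    n_markers: int = 20,
    marker_len: int = 1500,
    with_repeats: bool = False,
    segment_scale: float = DEFAULT_SEGMENT_SCALE,
    gain_sigma: float = DEFAULT_GAIN_SIGMA,
) -> Scenario:
    """The default study design: a 200 kb reference with 20 planted 1.5 kb
    markers (plus one 2-copy 3 kb repeat family when ``with_repeats``),
    sampled by 24 nuclei at covered fraction 0.4 — the shape of a 24-nuclei
    single-nucleus sequencing experiment at desk scale.
    """
    repeat_spec = (RepeatSpec("repfam1", 3000, 2),) if with_repeats else ()
    reference = make_reference(length, n_markers=n_markers, marker_len=marker_len,
                               repeat_spec=repeat_spec, seed=seed)
    profiles = [
        simulate_nucleus(reference, covered_fraction, segment_scale, gain_sigma,
                         seed=seed + 1 + i, nucleus_id=f"n{i:02d}")
        for i in range(n_nuclei)
    ]
    return Scenario(reference=reference, profiles=profiles, seed=seed)
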