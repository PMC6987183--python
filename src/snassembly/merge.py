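"""Consensus assembly of per-nucleus contig sets by mutual maximal extension.

Per-nucleus assemblies of the same genome are partial and mutually
redundant.  This module merges them into a consensus: candidate overlaps
come from motif-spacing signatures (:mod:`snassembly.fingerprint`), are
verified base-by-base, and only reciprocal-best ("mutual maximal") partners
are joined, which protects repeat boundaries from greedy chimeric joins.

The driver, :func:`consensus_merge`, pools all contigs, applies an optional
pre-merge length filter, removes fully contained contigs, and then iterates
the match→verify→select→merge cycle per motif (up to ``iterations_per_motif``
passes each, default 10, with early exit once a pass merges nothing),
repeating the whole motif cycle until a full cycle changes nothing.
Containment is swept again at the start of every cycle because merged
products can come to contain contigs that straddled a former junction.

Every structural event (merge, containment removal) is recorded in a
:class:`MergeLog`; replaying the log on the input pool reproduces the
output assembly exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .fingerprint import (
    DEFAULT_GAP_TOLERANCE,
    DEFAULT_MIN_RUN,
    FingerprintIndex,
    MotifFingerprint,
    MotifSet,
    SignatureMatch,
)
from .seqio import Contig, reverse_complement

DEFAULT_MIN_IDENTITY = 0.98
DEFAULT_MIN_OVERLAP_BP = 200

#: Pre-merge length-filter presets ("smaller than" is a strict <).
LENGTH_FILTER_PRESETS = (0, 500, 1000, 2000)

FWD = "+"
REV = "-"


class MergeError(RuntimeError):
    """Internal inconsistency between signature coordinates and sequences."""


@dataclass(frozen=True)
class VerifiedOverlap:
    """A base-level verified suffix–prefix overlap between oriented contigs.

    The overlap reads: the last ``overlap_bp`` bases of A oriented by
    ``a_strand`` match the first ``overlap_bp`` bases of B oriented by
    ``b_strand`` at ``identity``.  ``offset`` is where the overlap starts
    in A's oriented coordinates.
    """

    contig_a: str
    contig_b: str
    a_strand: str
    b_strand: str
    offset: int
    overlap_bp: int
    identity: float

    @property
    def orientation(self) -> str:
        return "forward" if self.a_strand == self.b_strand else "reverse"

    @property
    def end_a(self) -> tuple[str, str]:
        return (self.contig_a, "right" if self.a_strand == FWD else "left")

    @property
    def end_b(self) -> tuple[str, str]:
        return (self.contig_b, "left" if self.b_strand == FWD else "right")


@dataclass(frozen=True)
class MergeEvent:
    cycle: int
    motif: str
    iteration: int
    overlap: VerifiedOverlap
    result_id: str


@dataclass(frozen=True)
class ContainmentEvent:
    cycle: int
    contained_id: str
    container_id: str
    identity: float


@dataclass
class MergeLog:
    events: list[MergeEvent | ContainmentEvent] = field(default_factory=list)
    pass_counts: list[tuple[int, str, int, int, int]] = field(default_factory=list)
    # (cycle, motif, iteration, contigs_in, merges)

    @property
    def n_merges(self) -> int:
        return sum(1 for e in self.events if isinstance(e, MergeEvent))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("event\tcycle\tmotif\titeration\tcontig_a\tcontig_b\t"
                     "a_strand\tb_strand\toverlap_bp\tidentity\tresult_id\n")
            for e in self.events:
                if isinstance(e, MergeEvent):
                    o = e.overlap
                    fh.write(f"merge\t{e.cycle}\t{e.motif}\t{e.iteration}\t"
                             f"{o.contig_a}\t{o.contig_b}\t{o.a_strand}\t{o.b_strand}\t"
                             f"{o.overlap_bp}\t{o.identity:.4f}\t{e.result_id}\n")
                else:
                    fh.write(f"containment\t{e.cycle}\t.\t.\t{e.contained_id}\t"
                             f"{e.container_id}\t.\t.\t.\t{e.identity:.4f}\t.\n")
        return path


def length_filter(contigs: Sequence[Contig], min_len: int) -> list[Contig]:
    """Drop contigs strictly shorter than ``min_len``; order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be non-negative")
    return [c for c in contigs if len(c.sequence) >= min_len]


def _identity(a: str, b: str) -> float:
    """Ungapped fraction of matching bases between equal-length strings."""
    if len(a) != len(b):
        raise MergeError("identity comparison on unequal-length regions")
    if not a:
        return 0.0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((x == y).mean())


def oriented(contig: Contig, strand: str) -> str:
    return contig.sequence if strand == FWD else reverse_complement(contig.sequence)


def verify_overlap(
    contig_a: Contig,
    contig_b: Contig,
    match: SignatureMatch,
    a_strand: str = FWD,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> VerifiedOverlap | None:
    """Base-level check of a signature candidate; None if it fails thresholds.

    The candidate asserts that A's oriented suffix from ``match.offset``
    matches B's oriented prefix.  The comparison is ungapped.  Matches that
    would not extend either contig (offset 0, or B fully inside the
    overlap) are rejected here: those are containment relations, handled by
    the containment sweep, not extensions.
    """
    # match.orientation names B's absolute strand (the index stores both
    # orientations of every contig); A's strand is whatever the caller queried.
    b_strand = FWD if match.orientation == "forward" else REV
    seq_a = oriented(contig_a, a_strand)
    seq_b = oriented(contig_b, b_strand)
    overlap_bp = len(seq_a) - match.offset
    if match.offset < 0 or overlap_bp <= 0 or overlap_bp > len(seq_b):
        raise MergeError(
            f"signature offset {match.offset} out of range for "
            f"{contig_a.id} ({len(seq_a)} bp) vs {contig_b.id} ({len(seq_b)} bp)"
        )
    if match.offset == 0 or overlap_bp == len(seq_b):
        return None  # containment, not an extension
    if overlap_bp < min_overlap_bp:
        return None
    ident = _identity(seq_a[match.offset:], seq_b[:overlap_bp])
    if ident < min_identity:
        return None
    return VerifiedOverlap(contig_a.id, contig_b.id, a_strand, b_strand,
                           match.offset, overlap_bp, ident)


def _dedup_overlaps(overlaps: Iterable[VerifiedOverlap]) -> list[VerifiedOverlap]:
    """Collapse the two discoveries of one physical overlap (one per side)."""
    best: dict[frozenset, VerifiedOverlap] = {}
    for ov in sorted(overlaps, key=lambda o: (o.contig_a, o.a_strand, o.contig_b)):
        key = frozenset((ov.end_a, ov.end_b))
        if key not in best:
            best[key] = ov
    return list(best.values())


def select_mutual_maximal(overlaps: Sequence[VerifiedOverlap]) -> list[VerifiedOverlap]:
    """Reciprocal-best overlap selection, per contig end, vertex-disjoint.

    Each contig end's best partner is the verified overlap with the
    greatest ``overlap_bp`` (ties: higher identity, then lexicographically
    smaller partner id).  An overlap is selected iff it is the best of both
    ends it joins; the selected set is then made vertex-disjoint greedily
    in deterministic order, so one contig merges at most once per pass.
    """
    overlaps = _dedup_overlaps(overlaps)

    def partner(ov: VerifiedOverlap, end: tuple[str, str]) -> str:
        return ov.contig_b if end == ov.end_a else ov.contig_a

    best: dict[tuple[str, str], VerifiedOverlap] = {}
    for ov in overlaps:
        for end in (ov.end_a, ov.end_b):
            cur = best.get(end)
            if cur is None:
                best[end] = ov
                continue
            new_key = (ov.overlap_bp, ov.identity, *sorted([ov.contig_a, ov.contig_b]))
            cur_key = (cur.overlap_bp, cur.identity, *sorted([cur.contig_a, cur.contig_b]))
            if (new_key[0], new_key[1]) > (cur_key[0], cur_key[1]) or (
                new_key[:2] == cur_key[:2] and partner(ov, end) < partner(cur, end)
            ):
                best[end] = ov

    mutual = [ov for ov in overlaps if best.get(ov.end_a) is ov and best.get(ov.end_b) is ov]
    mutual.sort(key=lambda o: (-o.overlap_bp, -o.identity, o.contig_a, o.contig_b))
    used: set[str] = set()
    selected = []
    for ov in mutual:
        if ov.contig_a in used or ov.contig_b in used:
            continue
        used.update((ov.contig_a, ov.contig_b))
        selected.append(ov)
    return selected


def merge_pair(contig_a: Contig, contig_b: Contig, overlap: VerifiedOverlap) -> Contig:
    """Join two contigs across a verified overlap.

    Within the overlap, mismatched positions take the base from the longer
    contig (ties favour A): the longer contig has, on average, deeper merge
    support.  The merged length is ``len(A) + len(B) - overlap_bp``.
    """
    seq_a = oriented(contig_a, overlap.a_strand)
    seq_b = oriented(contig_b, overlap.b_strand)
    off, ovl = overlap.offset, overlap.overlap_bp
    consensus = seq_a[off:] if len(seq_a) >= len(seq_b) else seq_b[:ovl]
    merged_seq = seq_a[:off] + consensus + seq_b[ovl:]
    token = (f"{contig_a.id}:{overlap.a_strand}|{contig_b.id}:{overlap.b_strand}"
             f"|{off}|{ovl}")
    new_id = "m" + hashlib.sha1(token.encode()).hexdigest()[:12]
    return Contig(
        id=new_id,
        sequence=merged_seq,
        source_nuclei=contig_a.source_nuclei | contig_b.source_nuclei,
        merge_depth=max(contig_a.merge_depth, contig_b.merge_depth) + 1,
    )


# ---------------------------------------------------------------------------
# Containment removal
# ---------------------------------------------------------------------------

def _shingle_map(fps: Iterable[MotifFingerprint], min_run: int) -> dict:
    shingles: dict[tuple, set[str]] = {}
    for fp in fps:
        for f in (fp, fp.reversed()):
            for i in range(len(f.gaps) - min_run + 1):
                shingles.setdefault(f.gaps[i : i + min_run], set()).add(fp.contig_id)
    return shingles


def remove_contained(
    contigs: Sequence[Contig],
    motif_set: MotifSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[list[Contig], list[tuple[str, str, float]]]:
    """Drop every contig that is a >= min_identity substring of a kept one.

    Candidates come from shared gap-shingles (either strand); candidates
    are verified by banded infix alignment (edlib), with an exact substring
    check as a fallback for contigs too motif-poor to carry a shingle.
    Contigs are examined longest-first so containers are always kept;
    equal-length duplicates keep the lexicographically smaller id.
    Returns (kept contigs in input order, [(contained, container, identity)]).
    """
    order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    fps = {c.id: [MotifFingerprint.of(c, m) for m in motif_set] for c in contigs}
    by_motif = [
        _shingle_map((fps[c.id][j] for c in contigs), min_run)
        for j in range(len(tuple(motif_set)))
    ]
    by_id = {c.id: c for c in contigs}
    kept: list[Contig] = []
    kept_ids: set[str] = set()
    removed: list[tuple[str, str, float]] = []
    for c in order:
        candidates: set[str] = set()
        for j, _m in enumerate(motif_set):
            fp = fps[c.id][j]
            for f in (fp, fp.reversed()):
                for i in range(len(f.gaps) - min_run + 1):
                    candidates |= by_motif[j].get(f.gaps[i : i + min_run], set())
        candidates &= kept_ids
        container = None
        ident = 0.0
        max_dist = int((1.0 - min_identity) * len(c.sequence))
        rc = reverse_complement(c.sequence)
        for cid in sorted(candidates, key=lambda i: (-len(by_id[i].sequence), i)):
            host = by_id[cid].sequence
            for query in (c.sequence, rc):
                res = edlib.align(query, host, mode="HW", task="distance", k=max_dist)
                if res["editDistance"] != -1:
                    container, ident = cid, 1.0 - res["editDistance"] / len(c.sequence)
                    break
            if container:
                break
        if container is None:  # motif-poor fallback: exact substring only
            for k in kept:
                if c.sequence in k.sequence or rc in k.sequence:
                    container, ident = k.id, 1.0
                    break
        if container is None:
            kept.append(c)
            kept_ids.add(c.id)
        else:
            removed.append((c.id, container, ident))
    input_order = {c.id: i for i, c in enumerate(contigs)}
    kept.sort(key=lambda c: input_order[c.id])
    return kept, removed


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

class _FingerprintCache:
    def __init__(self) -> None:
        self._store: dict[tuple[str, str], MotifFingerprint] = {}

    def get(self, contig: Contig, motif: str) -> MotifFingerprint:
        key = (contig.id, motif)
        fp = self._store.get(key)
        if fp is None:
            fp = MotifFingerprint.of(contig, motif)
            self._store[key] = fp
        return fp


def _merge_pass(
    pool: dict[str, Contig],
    motif: str,
    cache: _FingerprintCache,
    min_run: int,
    gap_tolerance: int,
    min_identity: float,
    min_overlap_bp: int,
) -> list[tuple[VerifiedOverlap, Contig]]:
    """One match→verify→select→merge pass for one motif; mutates pool."""
    index = FingerprintIndex(min_run=min_run, gap_tolerance=gap_tolerance)
    fps = {cid: cache.get(c, motif) for cid, c in pool.items()}
    for fp in fps.values():
        index.add(fp)
    verified: list[VerifiedOverlap] = []
    for cid in sorted(pool):
        fp = fps[cid]
        for query, a_strand in ((fp, FWD), (fp.reversed(), REV)):
            for match in index.candidates(query):
                ov = verify_overlap(pool[match.contig_a], pool[match.contig_b],
                                    match, a_strand, min_identity, min_overlap_bp)
                if ov is not None:
                    verified.append(ov)
    results = []
    for ov in select_mutual_maximal(verified):
        merged = merge_pair(pool[ov.contig_a], pool[ov.contig_b], ov)
        del pool[ov.contig_a], pool[ov.contig_b]
        pool[merged.id] = merged
        results.append((ov, merged))
    return results


def consensus_merge(
    contig_sets: Sequence[Sequence[Contig]],
    motif_set: MotifSet | None = None,
    iterations_per_motif: int = 10,
    min_len: int = 0,
    min_run: int = DEFAULT_MIN_RUN,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
    max_cycles: int = 20,
) -> tuple[list[Contig], MergeLog]:
    """Merge per-nucleus contig sets into a consensus assembly.

    Returns the consensus contigs (sorted longest-first) and the merge log.
    An empty pool after length filtering yields an empty assembly.
    """
    if not contig_sets:
        raise ValueError("at least one contig set is required")
    motif_set = motif_set or MotifSet()
    pooled = [c for cs in contig_sets for c in cs]
    pooled = length_filter(pooled, min_len)
    log = MergeLog()
    if not pooled:
        return [], log
    if len({c.id for c in pooled}) != len(pooled):
        raise ValueError("duplicate contig ids across input sets")

    pool = {c.id: c for c in pooled}
    cache = _FingerprintCache()
    for cycle in range(1, max_cycles + 1):
        changed = 0
        kept, removed = remove_contained(list(pool.values()), motif_set,
                                         min_identity, min_run)
        for contained, container, ident in removed:
            log.events.append(ContainmentEvent(cycle, contained, container, ident))
            del pool[contained]
        changed += len(removed)
        for motif in motif_set:
            for iteration in range(1, iterations_per_motif + 1):
                n_in = len(pool)
                merges = _merge_pass(pool, motif, cache, min_run, gap_tolerance,
                                     min_identity, min_overlap_bp)
                log.pass_counts.append((cycle, motif, iteration, n_in, len(merges)))
                for ov, merged in merges:
                    log.events.append(MergeEvent(cycle, motif, iteration, ov, merged.id))
                changed += len(merges)
                if not merges:
                    break
        if changed == 0:
            break
    assembly = sorted(pool.values(), key=lambda c: (-len(c.sequence), c.id))
    return assembly, log


def replay_log(contig_sets: Sequence[Sequence[Contig]], log: MergeLog,
               min_len: int = 0) -> list[Contig]:
    """Re-apply a merge log to the input pool; must reproduce the assembly."""
    pool = {c.id: c for cs in contig_sets for c in length_filter(list(cs), min_len)}
    for e in log.events:
        if isinstance(e, ContainmentEvent):
            del pool[e.contained_id]
        else:
            ov = e.overlap
            merged = merge_pair(pool[ov.contig_a], pool[ov.contig_b], ov)
            if merged.id != e.result_id:
                raise MergeError(f"replay mismatch: {merged.id} != {e.result_id}")
            del pool[ov.contig_a], pool[ov.contig_b]
            pool[merged.id] = merged
    return sorted(pool.values(), key=lambda c: (-len(c.sequence), c.id))
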