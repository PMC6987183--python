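"""Sequence I/O and elementary sequence operations.

Contigs and paired-end read sets are the two currencies of the package:
per-nucleus assemblies enter as FASTA, per-nucleus reads as ``_1``/``_2``
FASTQ file pairs (optionally gzipped).  All coordinates are 0-based,
half-open.  Non-ACGT IUPAC codes are collapsed to ``N`` on read: amplified
single-nucleus data contains ambiguity calls, and the downstream merge
logic only needs exact bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_N = {c: "N" for c in "BDHKMRSVWYU"}
_CLEAN = str.maketrans({**_TO_N, **{c.lower(): v for c, v in _TO_N.items()}})


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input (names the offending line)."""


class SequenceError(ValueError):
    """Raised for invalid sequence content or degenerate inputs."""


@dataclass(frozen=True)
class Contig:
    """A DNA sequence with merge provenance.

    ``merge_depth`` counts the merge events that produced the contig; input
    contigs from a single-nucleus assembly have depth 0 and exactly one
    source nucleus.
    """

    id: str
    sequence: str
    source_nuclei: frozenset[str] = field(default_factory=frozenset)
    merge_depth: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceError(f"contig {self.id!r}: empty sequence")
        if not DNA_ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise SequenceError(f"contig {self.id!r}: non-ACGTN characters {bad}")
        if self.merge_depth == 0 and len(self.source_nuclei) > 1:
            raise SequenceError(
                f"contig {self.id!r}: unmerged contig must have a single source nucleus"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise SequenceError(f"read pair {self.id!r}: quality/sequence length mismatch")


@dataclass
class NucleusReadSet:
    """Paired-end reads attributed to one amplified nucleus."""

    nucleus_id: str
    reads: list[ReadPair]
    read_length: int

    def __post_init__(self) -> None:
        for pair in self.reads:
            if len(pair.seq1) != self.read_length or len(pair.seq2) != self.read_length:
                raise SequenceError(
                    f"nucleus {self.nucleus_id!r}, pair {pair.id!r}: "
                    f"mate length != read_length {self.read_length}"
                )


def clean_sequence(raw: str) -> str:
    """Uppercase and collapse any non-ACGT IUPAC code to N."""
    s = raw.upper().translate(_CLEAN)
    if not DNA_ALPHABET.issuperset(s):
        bad = sorted(set(s) - DNA_ALPHABET)
        raise SequenceError(f"characters {bad} are not valid IUPAC nucleotide codes")
    return s


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(contigs: Iterable[Contig | str]) -> float:
    """GC percentage over all contigs, N excluded from the denominator."""
    gc = at = 0
    for c in contigs:
        s = c.sequence if isinstance(c, Contig) else c
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise SequenceError("GC content undefined: no non-N bases in input")
    return 100.0 * gc / (gc + at)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _validate_fasta_lines(path: str | Path) -> None:
    # cheap structural pre-scan so errors can name the offending line
    n_records = 0
    header_line = 0
    have_seq = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line and not have_seq:
                    raise FastaFormatError(
                        f"{path}: header at line {header_line} has no sequence"
                    )
                header_line, have_seq = lineno, False
                n_records += 1
            else:
                if not header_line:
                    raise FastaFormatError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                have_seq = True
    if n_records == 0:
        raise FastaFormatError(f"{path}: empty file (no FASTA records)")
    if not have_seq:
        raise FastaFormatError(f"{path}: header at line {header_line} has no sequence")


def read_fasta(path: str | Path, nucleus_id: str | None = None) -> list[Contig]:
    """Read contigs from FASTA; ids are headers up to the first whitespace.

    ``nucleus_id`` attributes every contig in the file to one source nucleus
    (defaults to the file stem).
    """
    _validate_fasta_lines(path)
    src = nucleus_id if nucleus_id is not None else Path(path).name.split(".")[0]
    contigs = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            contigs.append(
                Contig(id=rec.id, sequence=clean_sequence(str(rec.seq)),
                       source_nuclei=frozenset({src}), merge_depth=0)
            )
    return contigs


def write_fasta(contigs: Sequence[Contig], path: str | Path, line_width: int = 80) -> Path:
    if not contigs:
        raise SequenceError("refusing to write an empty contig list")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"duplicate contig ids: {dup}")
    path = Path(path)
    with _open_text(path, "wt") as fh:
        records = (SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs)
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)
    return path


def read_fastq_pair(path1: str | Path, path2: str | Path, nucleus_id: str) -> NucleusReadSet:
    """Read a ``_1``/``_2`` FASTQ file pair into one nucleus read set."""
    pairs = []
    with _open_text(path1) as f1, _open_text(path2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for r1, r2 in zip(it1, it2, strict=True):
            pairs.append(ReadPair(
                id=r1.id,
                seq1=clean_sequence(str(r1.seq)), seq2=clean_sequence(str(r2.seq)),
                qual1="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                qual2="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            ))
    if not pairs:
        raise FastaFormatError(f"{path1}: no reads")
    read_length = len(pairs[0].seq1)
    return NucleusReadSet(nucleus_id=nucleus_id, reads=pairs, read_length=read_length)


def write_fastq_pair(read_set: NucleusReadSet, prefix: str | Path,
                     gzipped: bool = False) -> tuple[Path, Path]:
    suffix = ".fastq.gz" if gzipped else ".fastq"
    p1 = Path(f"{prefix}_1{suffix}")
    p2 = Path(f"{prefix}_2{suffix}")
    with _open_text(p1, "wt") as f1, _open_text(p2, "wt") as f2:
        for pair in read_set.reads:
            f1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
    return p1, p2


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> Path:
    """Write (chrom, start, end, name) truth intervals as 0-based half-open BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return path


def iter_kmers(sequence: str, k: int) -> Iterator[str]:
    for i in range(len(sequence) - k + 1):
        yield sequence[i : i + k]
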