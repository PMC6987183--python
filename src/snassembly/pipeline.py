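"""End-to-end workflow orchestration.

Three topologies turn per-nucleus read sets into one assembly:

1. assemble each nucleus separately, then merge the per-nucleus
   assemblies into a consensus (no normalization);
2. normalize each nucleus's reads to the target depth, assemble each,
   then merge into a consensus;
3. pool all reads, normalize once, assemble once — no merge stage.

Assembly engines are a boundary, not a re-implementation: the built-in
mock backend derives each nucleus's assembly from its simulated coverage
profile, and an external command template can substitute a real assembler.
Every run produces a provenance manifest (stages, parameters, seed, input
checksums) so identical config + inputs + seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import yaml

from .fingerprint import DEFAULT_GAP_TOLERANCE, DEFAULT_MIN_RUN, DEFAULT_MOTIFS, MotifSet
from .merge import DEFAULT_MIN_IDENTITY, DEFAULT_MIN_OVERLAP_BP, MergeLog, consensus_merge
from .normalize import DEFAULT_K, DEFAULT_TARGET_DEPTH, normalize_reads, pool_read_sets
from .seqio import Contig, NucleusReadSet, read_fasta, write_fastq_pair
from .simulate import NucleusProfile, ReferenceTruth, mock_assemble


class ConfigError(ValueError):
    pass


class AssemblerError(RuntimeError):
    pass


@dataclass(frozen=True)
class WorkflowConfig:
    """Parameters of one workflow run; validation enforces the topology rules."""

    workflow: int
    normalization_target: int = DEFAULT_TARGET_DEPTH
    k: int = DEFAULT_K
    min_len: int = 0
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    iterations_per_motif: int = 10
    min_run: int = DEFAULT_MIN_RUN
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP
    assembler: str = "mock"
    external_command: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in (1, 2, 3):
            raise ConfigError(f"unknown workflow {self.workflow}; expected 1, 2 or 3")
        if self.assembler not in ("mock", "external"):
            raise ConfigError(f"unknown assembler backend {self.assembler!r}")
        if self.assembler == "external":
            if not self.external_command:
                raise ConfigError("external assembler requires a command template")
            for ph in ("{reads1}", "{reads2}", "{out}"):
                if ph not in self.external_command:
                    raise ConfigError(f"command template missing placeholder {ph}")
        MotifSet(self.motifs)  # validates strand symmetry

    @property
    def normalizes(self) -> bool:
        return self.workflow in (2, 3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "motifs" in data:
            data["motifs"] = tuple(data["motifs"])
        return cls(**data)


class AssemblerBackend(Protocol):
    def assemble_nucleus(self, read_set: NucleusReadSet) -> list[Contig]: ...

    def assemble_pooled(self, pooled: NucleusReadSet,
                        nucleus_ids: Sequence[str]) -> list[Contig]: ...


def _union_intervals(profiles: Sequence[NucleusProfile]) -> list[tuple[int, int]]:
    ivs = sorted(iv for p in profiles for iv in p.covered_intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class MockAssembler:
    """Profile-driven stand-in assembler.

    Emits each nucleus's covered intervals as contigs (see
    :func:`snassembly.simulate.mock_assemble`); for pooled input it
    assembles the union of the nuclei's covered intervals, mimicking a
    real assembler seeing the combined reads.  Read depth is ignored, so
    normalization is a no-op upstream of this backend — useful for
    isolating merge behaviour from assembler behaviour in tests.
    """

    reference: ReferenceTruth
    profiles: dict[str, NucleusProfile]
    min_contig_len: int = 0
    break_prob: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def _profile_for(self, nucleus_id: str) -> NucleusProfile:
        try:
            return self.profiles[nucleus_id]
        except KeyError:
            raise AssemblerError(f"mock backend has no profile for {nucleus_id!r}")

    def assemble_nucleus(self, read_set: NucleusReadSet) -> list[Contig]:
        profile = self._profile_for(read_set.nucleus_id)
        id_hash = int.from_bytes(
            hashlib.sha1(read_set.nucleus_id.encode()).digest()[:4], "big")
        sub_seed = (self.seed * 131 + id_hash) % (2**31)
        return mock_assemble(self.reference, profile, self.min_contig_len,
                             self.break_prob, self.error_rate, seed=sub_seed)

    def assemble_pooled(self, pooled: NucleusReadSet,
                        nucleus_ids: Sequence[str]) -> list[Contig]:
        profiles = [self._profile_for(nid) for nid in nucleus_ids]
        union = _union_intervals(profiles)
        pooled_profile = NucleusProfile(
            nucleus_id=pooled.nucleus_id,
            covered_intervals=union,
            gains=[1.0] * len(union),
            reference_length=len(self.reference),
        )
        return mock_assemble(self.reference, pooled_profile, self.min_contig_len,
                             self.break_prob, self.error_rate, seed=self.seed)


@dataclass
class ExternalCommandAssembler:
    """Run a user-supplied assembler command on FASTQ mates.

    The template must contain ``{reads1}``, ``{reads2}`` and ``{out}``
    placeholders; the produced FASTA is validated before use.
    """

    command_template: str
    workdir: Path | None = None

    def _run(self, read_set: NucleusReadSet) -> list[Contig]:
        with tempfile.TemporaryDirectory(dir=self.workdir) as td:
            prefix = Path(td) / read_set.nucleus_id
            r1, r2 = write_fastq_pair(read_set, prefix)
            out = Path(td) / f"{read_set.nucleus_id}.contigs.fasta"
            cmd = self.command_template.format(reads1=r1, reads2=r2, out=out)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise AssemblerError(
                    f"assembler exited {proc.returncode} for {read_set.nucleus_id}: "
                    f"{proc.stderr.strip()}")
            if not out.exists() or out.stat().st_size == 0:
                raise AssemblerError(
                    f"assembler produced no output for {read_set.nucleus_id}")
            return read_fasta(out, nucleus_id=read_set.nucleus_id)

    def assemble_nucleus(self, read_set: NucleusReadSet) -> list[Contig]:
        return self._run(read_set)

    def assemble_pooled(self, pooled: NucleusReadSet,
                        nucleus_ids: Sequence[str]) -> list[Contig]:
        return self._run(pooled)


def _checksum(read_set: NucleusReadSet) -> str:
    h = hashlib.sha256()
    for p in read_set.reads:
        h.update(p.id.encode())
        h.update(p.seq1.encode())
        h.update(p.seq2.encode())
    return h.hexdigest()[:16]


def _contig_checksum(contigs: Sequence[Contig]) -> str:
    h = hashlib.sha256()
    for c in sorted(contigs, key=lambda c: c.id):
        h.update(c.id.encode())
        h.update(c.sequence.encode())
    return h.hexdigest()[:16]


@dataclass
class WorkflowResult:
    assembly: list[Contig]
    merge_log: MergeLog | None
    manifest: dict

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)
        return path


def run_workflow(
    config: WorkflowConfig,
    per_nucleus_inputs: Sequence[NucleusReadSet] | Sequence[Sequence[Contig]],
    backend: AssemblerBackend | None = None,
) -> WorkflowResult:
    """Execute one workflow topology on per-nucleus inputs.

    Workflows 2 and 3 require read sets.  Workflow 1 also accepts
    pre-built per-nucleus contig lists, in which case the assembler
    backend is bypassed.
    """
    if not per_nucleus_inputs:
        raise ConfigError("no per-nucleus inputs")
    inputs_are_reads = isinstance(per_nucleus_inputs[0], NucleusReadSet)
    if not inputs_are_reads and config.workflow != 1:
        raise ConfigError("workflows 2 and 3 require read sets, not contig sets")
    if inputs_are_reads and backend is None:
        if config.assembler == "external":
            backend = ExternalCommandAssembler(config.external_command)
        else:
            raise ConfigError("mock backend must be constructed with simulation truth")

    manifest: dict = {
        "workflow": config.workflow,
        "seed": config.seed,
        "parameters": {
            "normalization_target": config.normalization_target if config.normalizes else None,
            "k": config.k, "min_len": config.min_len,
            "motifs": list(config.motifs),
            "iterations_per_motif": config.iterations_per_motif,
            "min_run": config.min_run, "gap_tolerance": config.gap_tolerance,
            "min_identity": config.min_identity,
            "min_overlap_bp": config.min_overlap_bp,
            "assembler": config.assembler,
        },
        "inputs": [],
        "stages": [],
    }

    motif_set = MotifSet(config.motifs)
    merge_kwargs = dict(
        motif_set=motif_set, iterations_per_motif=config.iterations_per_motif,
        min_len=config.min_len, min_run=config.min_run,
        gap_tolerance=config.gap_tolerance, min_identity=config.min_identity,
        min_overlap_bp=config.min_overlap_bp,
    )

    if inputs_are_reads:
        read_sets: list[NucleusReadSet] = list(per_nucleus_inputs)  # type: ignore
        manifest["inputs"] = [
            {"nucleus": rs.nucleus_id, "pairs": len(rs.reads), "sha256": _checksum(rs)}
            for rs in read_sets
        ]
        if config.workflow == 3:
            pooled = pool_read_sets(read_sets)
            manifest["stages"].append({"stage": "pool", "pairs": len(pooled.reads)})
            normalized, report = normalize_reads(pooled, config.normalization_target,
                                                 config.k)
            manifest["stages"].append({"stage": "normalize",
                                       "pairs_in": report.pairs_in,
                                       "pairs_kept": report.pairs_kept})
            assembly = backend.assemble_pooled(
                normalized, [rs.nucleus_id for rs in read_sets])
            manifest["stages"].append({"stage": "assemble_pooled",
                                       "contigs": len(assembly)})
            assembly = sorted(assembly, key=lambda c: (-len(c.sequence), c.id))
            merge_log = None
        else:
            contig_sets = []
            for rs in read_sets:
                if config.workflow == 2:
                    rs, report = normalize_reads(rs, config.normalization_target,
                                                 config.k)
                    manifest["stages"].append({"stage": "normalize",
                                               "nucleus": rs.nucleus_id,
                                               "pairs_in": report.pairs_in,
                                               "pairs_kept": report.pairs_kept})
                contigs = backend.assemble_nucleus(rs)
                manifest["stages"].append({"stage": "assemble",
                                           "nucleus": rs.nucleus_id,
                                           "contigs": len(contigs)})
                contig_sets.append(contigs)
            assembly, merge_log = consensus_merge(contig_sets, **merge_kwargs)
            manifest["stages"].append({"stage": "consensus_merge",
                                       "merges": merge_log.n_merges,
                                       "contigs_out": len(assembly)})
    else:
        contig_sets = [list(cs) for cs in per_nucleus_inputs]  # type: ignore
        manifest["inputs"] = [
            {"contig_set": i, "contigs": len(cs), "sha256": _contig_checksum(cs)}
            for i, cs in enumerate(contig_sets)
        ]
        assembly, merge_log = consensus_merge(contig_sets, **merge_kwargs)
        manifest["stages"].append({"stage": "consensus_merge",
                                   "merges": merge_log.n_merges,
                                   "contigs_out": len(assembly)})

    manifest["output"] = {"contigs": len(assembly),
                          "sha256": _contig_checksum(assembly)}
    return WorkflowResult(assembly=list(assembly), merge_log=merge_log,
                          manifest=manifest)
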