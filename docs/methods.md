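# Methods

## The merge model

The consensus assembler treats per-nucleus assemblies as redundant,
partial tilings of one underlying genome. Its unit of evidence is the
*motif-spacing fingerprint*: for a motif m and contig s, the ordered list
of start positions of exact occurrences of m in s (overlapping
occurrences included) and the gaps between consecutive occurrences. The
motif set — `CATG, CTAG, GTAC, GATC, TATA, ATAT, GC` — consists entirely
of reverse-complement palindromes, which is load-bearing: an occurrence
at position p on one strand is an occurrence at L−|m|−p on the other, so
the reverse-complement fingerprint is the reversed gap list and candidate
search never needs to know input strands. A non-palindromic motif is
rejected at configuration time.

A candidate overlap between contigs A and B is an alignment in which a
suffix of A's gap list equals a prefix of B's, element-wise within
±`gap_tolerance` (default 0), with at least `min_run` gaps (default 4,
i.e. five shared occurrences). Candidates are generated by hashing
length-`min_run` gap windows: with zero tolerance, any qualifying run
must begin with B's gap-list prefix appearing as a window of A's, so the
index finds exactly what an all-pairs scan would; with nonzero tolerance
the index is bypassed and pairs are matched directly. Both orientations
of every contig are indexed and both orientations of every contig are
used as queries, so head–head and tail–tail overlaps are found as well as
head–tail; the two discoveries of one physical overlap (one from each
side) are collapsed to a canonical representative before selection.

Spacing identity does not imply sequence identity, so every candidate is
verified by an ungapped base-by-base comparison of the implied overlap.
An overlap is retained only if it spans at least `min_overlap_bp`
(default 200) at identity at least `min_identity` (default 0.98). MDA
produces low-error sequence, which is why exact gap matching and a high
identity floor are the defaults; both are exposed in configuration.

Merging is *mutual maximal*: per contig end (left and right are tracked
separately), the best partner is the retained overlap with the greatest
length, ties broken by higher identity and then lexicographically smaller
partner id; a pair is merged only if each end is the other's best. The
selected pairs of a pass are made vertex-disjoint greedily in
deterministic order, all merged simultaneously, and only the merged
products are re-fingerprinted. Within the overlap, mismatched positions
take the base of the longer contig (ties favour the first-named contig);
the merged contig's id is a hash of the two inputs and the overlap
geometry, so outputs do not depend on input order.

The driver pools all input contigs, applies the optional pre-merge length
filter (presets 0/500/1000/2000 bp; "smaller than" is strict), removes
fully contained contigs, and then runs up to ten match–verify–select–merge
passes per motif, in motif order, with early exit once a pass merges
nothing; the whole motif cycle repeats while anything changed, up to a
cycle cap of 20 (contig count strictly decreases, so the cap is never the
binding constraint in practice). Containment is swept again at the start
of every cycle: a merged product can come to contain a contig that
straddled a former junction, and such a contig can never merge by
suffix–prefix extension. Containment candidates come from shared gap
windows on either strand and are verified by banded infix alignment
(edlib), with an exact substring check as fallback for motif-poor
contigs; longest contigs are examined first so containers are always
kept. Every merge and containment event is logged, and replaying the log
on the input pool reproduces the output exactly.

Two readings of the iteration scheme were possible (ten iterations nested
per motif, or ten global cycles); the per-motif nesting was adopted, with
the outer convergence loop making the choice immaterial for the final
assembly. Likewise candidates are recomputed incrementally (merged
products only) rather than from scratch each pass; the unit tests compare
small instances against full recomputation via the order-robustness and
idempotence properties.

## Digital normalization

Reads are normalized in a single streaming pass over pairs, in input
order. The depth estimate reported for a pair is the median (lower-middle
convention) of the counts of its canonical k-mers (k=31, canonical = the
lexicographic minimum of k-mer and reverse complement; exact hash-map
counting) in an index accumulated from kept pairs only. The *keep
decision*, however, is conservative: a pair is kept only while none of
its k-mers has reached the target count. A median keep-rule equilibrates
above the target wherever coverage is positionally heterogeneous — the
upper half of a pair's counts is ignored, so saturated positions keep
being pushed higher by pairs straddling unsaturated ones (measured on 50×
uniform coverage normalized to 10×: kept depth ≈ 13.6×, with only ~22% of
kept pairs at or below the target post hoc). The saturation rule caps
every k-mer count in the kept set at the target by construction (up to
rare double-counts when mates overlap), so re-estimating kept pairs
against the kept-only index stays at or below the target, and the
retained fraction on uniform depth D tracks target/D. Pairs are atomic —
mates are kept or dropped together — and the kept set is always a
subsequence of the input, so per-nucleus and pooled normalization are the
same operation applied to different concatenations.

## The simulator

The generator emulates exactly the features of single-nucleus data the
method is sensitive to, and no more:

- **Reference**: i.i.d. bases at a target GC of 0.28 (AT-rich, as typical
  for AM fungal genomes), with planted features placed by rejection
  sampling: `n_markers` distinct random single-copy marker genes (default
  20 × 1.5 kb) and optional repeat families (each ≥2 copies of a mutated
  consensus, default 99% copy identity). Truth coordinates are 0-based
  half-open and exportable as BED.
- **Per-nucleus coverage**: the reference is cut into segments with
  exponential lengths (mean `segment_scale` = 20 kb), each segment is
  covered independently with probability `mean_covered_fraction`
  (default 0.4), and each maximal covered interval receives one lognormal
  amplification gain (σ = 1). This two-parameter dropout+gain model
  reproduces the phenomenology that matters — partial, high-variance
  nuclei whose union approaches completeness following 1−(1−c)^n — without
  modelling MDA's branching chemistry. With a 200 kb reference there are
  only ~10 segments per nucleus, so realized covered fractions scatter
  around the nominal c with SD ≈ 0.17; the canonical 24-nucleus scenario
  spans realized fractions from 0 to 0.7, which is the realistic regime
  (and means some simulated nuclei legitimately contribute nothing).
- **Reads**: pairs drawn from covered intervals at rates proportional to
  gain × length, inserts fully inside an interval (amplified fragments do
  not cross dropout boundaries), optional per-base substitution errors,
  constant qualities.
- **Mock assemblies**: each covered interval emitted as one contig,
  optionally broken (Poisson breaks per kb) and error-mutated. Contigs of
  one nucleus share no overlap with each other — all redundancy in a pool
  comes from other nuclei — and the backend ignores read depth, which is
  what makes "workflow 1 ≡ workflow 2 on error-free input" a clean test
  of the merge stage in isolation.

What the simulator does *not* emulate: chimeric MDA artefacts,
contamination, indel errors, quality-score structure, or any real
assembler's contiguity behaviour. Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the merge/normalize/evaluate
logic under controlled coverage bias, not performance on real MDA
libraries.

## Evaluation

Assembly statistics follow the standard definitions (N50 = length of the
shortest contig in the minimal set of longest contigs holding half the
assembly; GC% excludes N from the denominator). Marker completeness
locates each planted marker by exact 21-mer seeding (stride 10 plus the
final k-mer, both strands) followed by ungapped evaluation on each seed
diagonal, truncated at contig boundaries; placements within half a marker
length on the same contig and strand are one locus. A marker is
*complete* if one locus covers ≥95% of it at ≥95% identity, *duplicated*
if two or more such loci exist, *fragmented* if the best qualifying
coverage falls in [20%, 95%), otherwise *missing*. The thresholds are
configuration constants, chosen as round numbers comparable to common
ortholog-completeness practice; the [20,95) fragmentation band is a
stand-in convention, not a claim of equivalence with any external tool.
The single-copy duplication check counts distinct ≥95%/≥95% loci per
gene.

The saturation analysis draws random combinations of n distinct nuclei
(without replacement within a combination, independent across
replicates), runs the chosen workflow on each, and reports mean and SEM
(sd/√r, undefined at r=1) of completeness, size and N50 per n. The
default replicate plan is 3 replicates for n ≤ 12 and 1 beyond; the
plateau measurement in the acceptance run uses 6 replicates for n ≤ 12 —
the crossing-point of the completeness curve is the one estimate here
that is sensitive to replicate noise, so it gets the variance-minimizing
end of the 3–6 replicate design. The plateau is the smallest n whose mean
completeness *strictly* exceeds 95% of the 24-nuclei value: replicate
means over a discrete 20-marker set land exactly on the threshold
routinely, and a value at the threshold is not past it. When the measured
curve is compared with the analytic union-coverage curve, the per-n
uncertainty uses the empirical SEM with the binomial standard error
√(p(1−p)/(markers×replicates)) as a floor, because 20 discrete markers ×
few replicates can produce an empirical SEM of exactly zero.

## Problem sizes

The canonical study used throughout tests and the acceptance script is a
200 kb reference, 20 markers × 1.5 kb, 24 nuclei at c = 0.4 (one 2-copy
3 kb repeat family where repeats are relevant) — structured like a
24-nucleus sequencing design at a scale where every end-to-end property
runs in seconds to a couple of minutes. Normalization checks use 10–20 kb
references at 30–50× simulated depth. These sizes are the package's
calibration choices; all are parameters.

## Known limitations

- Overlap verification is ungapped; an indel inside a true overlap breaks
  both the spacing signature downstream of it and the base comparison, so
  indel-rich data would fragment rather than mis-join.
- Contigs too motif-poor to carry a `min_run` gap window (possible for
  very short or low-complexity sequence) can only be removed by exact
  containment, never merged.
- The consensus rule (longer contig wins) is a depth-free heuristic; with
  a real assembler backend, coverage-aware consensus would be preferable.
- Workflow 3 requires an assembler backend that accepts pooled reads; the
  built-in mock backend derives it from simulation truth, so workflow 3
  on real data needs the external-command backend.
- The CLI `run` command drives workflow 1 from a simulation directory;
  workflows 2 and 3 are exercised through the library API, which is where
  the pluggable backend lives.
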