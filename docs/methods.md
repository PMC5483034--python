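# Methods

## Problem and approach

Query-side parallelization of similarity search is sound because each query
record is scored against the database independently, and report-level
statistics (bit score, E-value) depend only on the query record and the
database as a whole. `dcsearch` therefore splits the *query* file, never the
database and never an individual sequence, runs one search task per chunk,
and merges the tabular outputs in task order.

## Partitioning rule

Input records are kept in file order and assigned to *contiguous* chunks.
Contiguity is load-bearing twice over: it makes the single greedy pass
cheap, and it means concatenating chunk outputs in task-index order restores
the exact output order of an unsplit run — the merge step is pure
concatenation.

For chunk *i* the pass computes a remaining-aware threshold
`thr_i = R_i / k_i` (residues not yet assigned over chunks not yet closed)
and accumulates records until the running total meets or exceeds `thr_i`
("meet-or-exceed" rather than strictly exceed: with a strict comparison an
input of N equal records requested as N chunks would collapse to roughly
N/2 chunks). Two boundary rules:

* **Record reservation.** A chunk never consumes so many records that a
  later chunk would be left empty (one record is reserved per unclosed
  chunk). This guarantees exactly `min(N, record count)` chunks. Without
  it, a short-records-then-long-record input such as lengths `[1,1,1,9]`
  with N = 4 would close its first chunk only after three records and
  produce two chunks instead of four. A chunk closed early by this rule may
  fall below its threshold; that is the accepted trade-off.
* **Oversized records.** A record longer than the threshold forms or
  terminates a chunk by itself; sequences are never split internally.

**Balance bound.** Every chunk satisfies
`chunk length ≤ T/N + max_record_length`. While thresholds bind, each closed
chunk has length ≥ its threshold, so the remaining per-chunk average
`R_i/k_i` is non-increasing and every threshold is ≤ T/N; a closing record
overshoots by less than one record length, and the final chunk's length is
exactly `R/1 ≤ T/N`. Once the reservation rule binds, every later chunk is
a single record, which satisfies the bound trivially. The bound is also
asserted on 1,000 random instances in the test suite, and an exhaustive
enumeration oracle (all contiguous partitions of ≤ 12 records into ≤ 4
chunks) confirms the greedy maximum chunk is within one record length of
the optimal contiguous makespan.

Non-contiguous assignments (LPT/bin-packing) could balance slightly better
but would break concatenation-order merging; they are deliberately out of
scope.

## Mock engine

The mock engine exists to make the pipeline's contract testable, not to
approximate real aligner sensitivity. It scores each query-subject pair by
their longest common substring (case-insensitive, exact, ungapped, forward
orientation only; ties broken by smallest query start, then smallest
subject start; the kernel is verified against a brute-force enumeration).
A match of length `L ≥ min_match` (default 8 residues, comfortably above
chance for the fixture sizes used) becomes a hit with

```
bitscore = 2·L        evalue = m · n · 2^(−bitscore)
```

where `m` is the query record length and `n` the total database length.
This reproduces the structural property that matters — E-values are
functions of the intact database and are invariant under query splitting —
while remaining exactly computable. Output is rendered byte-stably
(identity 100.00, E-value in two-significant-digit scientific notation,
bit score with one decimal) in two tabular styles: plain 12-column rows
(outfmt 6) and a commented style (outfmt 7) with a three-line comment block
(`# Query:`, `# Fields:`, `# <k> hits found`) for every query including
zero-hit ones. No run-level header or trailer is emitted, so a chunk file
is a pure concatenation of per-query output; the commented style is treated
as the modern equivalent of the legacy commented tabular dialect, and
per-query blocks are what make merged query accounting checkable.

## Scheduling and error handling

Cluster execution targets SGE array jobs only: the emitter writes a POSIX
shell script with `#$ -t 1-<task_count>`, selects the chunk by zero-padding
`$SGE_TASK_ID` into the `query_<k>.fasta` naming scheme, and persists each
task's exit code to `tasks/task_<k>.exit` — SGE does not report per-task
exit codes to the submitter, and the error log needs them after the fact.
Scripts are emitted, never submitted, and failed tasks are never retried
automatically: the intended workflow is to read the error log (one
tab-separated line per failed task: id, chunk file, exit code or `missing`,
message; an existing *empty* log is the positive signal of a clean run) and
re-run just the offending chunk. Local mode runs the same per-task command
path under a thread pool (tasks are subprocesses or I/O-bound, so threads
suffice) and writes the same sentinel files, which keeps desk-scale runs
faithful to cluster runs and lets `collect` work on both. Merging refuses
to proceed while any task failed; a silently partial merged file would mask
missing queries.

## Makespan simulator

Task time is modeled as `per_task_overhead + cost_per_residue · chunk
length` — affine in chunk residue length, encoding the empirical behaviour
that search time tracks sequence length rather than record count. Makespan
is the slowest task; speed-up is serial time over makespan, so with zero
overhead `1 ≤ speedup ≤ n_workers`. The simulator compares the greedy
length-balanced partition with a contiguous equal-record-count split. It
makes no wall-clock claims: absolute timings are hardware-dependent and out
of scope; the simulator's job is the qualitative shape (near-ideal scaling
for length-balanced splits, roughly half-ideal for count-balanced splits on
longest-first-sorted inputs). Split and merge costs can be represented via
`per_task_overhead`, but no calibration for them is claimed.

## Synthetic data

`synth_queryset` draws record lengths from one of three laws: `uniform(lo,
hi)`, `lognormal(mu, sigma)` (the right-skewed shape typical of transcript
length distributions; defaults around `mu=4.5–5, sigma=0.8` give a median
near 100–150 residues), or `descending(start, step)` (longest-first
arithmetic order, emulating de novo assembler output, the worst case for
count-balanced splitting). Residues are i.i.d. uniform over the DNA or
20-letter protein alphabet. `synth_subject_db` embeds, per subject, one
verbatim substring of a designated query (`planted_match` residues, default
subject length 200), guaranteeing the mock engine a hit of at least that
length for that pair. All generators run off a named seed and are
reproducible.

What the synthetic data does *not* emulate: real base composition,
repeats, homology that is similar-but-not-identical, gapped alignment, or
reverse-strand matches. Passing tests therefore demonstrate the *pipeline
contract* — balanced splitting, faithful scheduling, byte-exact merging —
not retrieval sensitivity on biological sequences; with a real BLAST+
engine the same invariance holds because the statistics share the same
dependence on query and database only.

## Problem sizes and numerical choices

The test suite uses 1,000 random query sets (≤ 500 records) for partition
invariants, 400 small instances against the exhaustive partition oracle,
20 planted query/database pairs × chunk counts {2, 4, 16} × both tabular
styles for merge equivalence, and 100 descending instances plus a
4,000-record fine-grained set (largest record < 1/(10·n) of the total for
n ≤ 32) for the simulator; the whole suite runs in well under a minute per
file on one CPU. E-values below double-precision underflow render as
`0.00e+00`, which is byte-stable and compares equal across split and
unsplit runs. Duplicate query ids are tolerated with a warning; empty
files, leading non-FASTA text and empty-sequence records are hard errors.

## Known limitations

* Only the SGE dialect is emitted; the emitter is a single function so
  SLURM/PBS dialects are future drop-ins.
* The mock engine is ungapped/exact/forward-only by design.
* `run` does not wrap `makeblastdb`; real databases are assumed pre-built.
* Failed tasks are reported, not resubmitted.
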