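# dcsearch

A scheduler-aware divide-and-conquer driver for sequence-similarity search.

Large homology searches (BLAST+ and tools with similar execution profiles)
are embarrassingly parallel on the query side, but doing the split by hand
loses time two ways: unevenly sized pieces leave most cluster cores idle
while the biggest piece finishes, and re-assembling per-piece output and
failures is error-prone. `dcsearch` automates the whole loop for anyone
running large query sets against a fixed database on a workstation or an
SGE-managed cluster:

1. **split** a multi-FASTA query into at most *N* *contiguous* chunks of
   approximately equal total residue length — balanced by length, not record
   count, because search time scales with sequence length;
2. **run** one search task per chunk, either through a local worker pool or
   by emitting a Sun Grid Engine *array job* script (each task picks its
   chunk via `$SGE_TASK_ID`);
3. **merge** the per-task tabular outputs, in task order, into a file
   identical to what one unsplit run would have produced, and write a
   per-task error log so a failed chunk can be re-run alone.

## The model

Let the query set have records with lengths `l_1 … l_m`, total `T`, and let
`N` be the requested chunk count. The partitioner is a single greedy pass:
for each chunk it computes a remaining-aware threshold
`thr = (remaining residues) / (remaining chunks)` and accumulates records
until the chunk's length meets or exceeds `thr`. This yields exactly
`min(N, m)` chunks with the provable balance bound

```
max chunk length  ≤  T/N + max_i l_i
```

so with task time proportional to chunk length, the parallel speed-up
approaches `N` whenever no single record dominates the input.

Correctness of merging rests on a property of the E-value: for a hit with
bit score `S`, query length `m` and database size `n`, `E ∝ m·n·2^(−S)`.
Nothing in that formula depends on which chunk a query sits in — the
database is untouched by query-side splitting — so a split run must
reproduce the unsplit report exactly. The package ships a deterministic
**mock engine** (longest-common-substring scoring with exactly this E-value
structure) so that guarantee is tested byte-for-byte without BLAST+
installed, plus an idealized makespan simulator that quantifies the benefit
of length-balanced over count-balanced splitting.

## Worked example

```sh
python examples/makespan_speedup.py
```

simulates a 1024-transcript, longest-first-sorted query (the order de novo
assemblers emit) on an idealized cluster where task time is proportional to
chunk residue length:

```
 workers  length-balanced  count-balanced
       1            1.00x           1.00x
       8            7.90x           4.98x
      16           15.75x           9.70x
      32           30.48x          19.14x
      64           58.51x          38.04x
```

Count-balanced splitting piles the longest transcripts into the first chunk
and tops out near half the ideal speed-up; length-balanced chunks keep every
worker busy. `examples/mock_search_merge.py` shows the merge guarantee —
it ends with `merged output byte-identical to unsplit run: True` — and
`examples/split_and_plan.py` and `examples/sge_array_script.py` demonstrate
partition diagnostics and the emitted array script.

The same workflow from the shell:

```sh
dcsearch run --query queries.fasta --chunks 16 --db subjects.fasta \
         --engine mock --workers 8 --work-dir run/
dcsearch run --query queries.fasta --chunks 256 --engine blast \
         --program blastx --db swissprot --evalue 1e-10 \
         --mode sge-script --work-dir run/   # then: cd run && qsub array_job.sh
dcsearch collect --work-dir run/             # after the array job finishes
```

`run` exits 0 only when every task succeeded and the merge completed; on
failures the merge is refused and `run/dcsearch.err` lists one line per
failed task (task id, chunk file, exit code, message).

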