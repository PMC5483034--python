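"""Partition a query set into length-balanced chunks and inspect the balance.

Builds a 200-record synthetic transcript set with log-normal lengths, plans
a 8-chunk contiguous partition, materializes the chunk FASTA files and
prints the balance diagnostics.
"""

import tempfile
from pathlib import Path

from dcsearch import materialize_chunks, partition_stats, plan_partition, synth_queryset

qs = synth_queryset(200, law=("lognormal", 5.0, 0.8), seed=1)
print(f"{len(qs)} records, {qs.total_length} residues, longest {qs.max_record_length}")

plan = plan_partition(qs, 8)
with tempfile.TemporaryDirectory() as tmp:
    plan = materialize_chunks(plan, qs, Path(tmp))
    for c in plan.chunks:
        print(f"  chunk {c.index}: records {c.first_record}-{c.last_record} "
              f"({c.n_records} records, {c.total_length} residues) -> {c.file_path.name}")

stats = partition_stats(plan)
print(f"max/mean chunk length = {stats.max_over_mean:.4f}  (1.0 would be perfect)")
print(f"coefficient of variation = {stats.cv:.4f}")
bound = qs.total_length / 8 + qs.max_record_length
print(f"every chunk <= T/N + longest record = {bound:.0f}: "
      f"{all(c.total_length <= bound for c in plan.chunks)}")
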