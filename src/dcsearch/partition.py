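"""Length-balanced contiguous partitioning of a query set.

Search run time scales with total residue length, not record count, so a
query file is subdivided into at most N *contiguous* chunks of approximately
equal total length. The partitioner is a single greedy pass in record order:
for each chunk it computes a remaining-aware threshold

    thr_i = (residues not yet assigned) / (chunks not yet closed)

and accumulates records until the chunk's cumulative length meets or exceeds
``thr_i``; the final chunk takes everything left. Two refinements keep the
plan well-formed on adversarial inputs:

* a chunk never takes so many records that a later chunk would be left
  empty (one record is reserved per remaining chunk), which guarantees
  exactly ``min(n_chunks, n_records)`` chunks;
* a record is never split internally — an oversized record simply forms or
  terminates a chunk by itself.

These rules give the provable balance bound

    every chunk total  <=  total_length / n_chunks  +  max_record_length,

because the remaining per-chunk average never grows while thresholds bind,
and once the record-reservation cap binds every later chunk is a single
record.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, replace
from pathlib import Path

from .fasta_io import QuerySet, write_fasta

__all__ = [
    "ChunkAssignment",
    "PartitionPlan",
    "PartitionStats",
    "chunk_file_name",
    "plan_partition",
    "partition_lengths",
    "materialize_chunks",
    "partition_stats",
    "write_manifest",
    "read_manifest",
    "MANIFEST_NAME",
]

MANIFEST_NAME = "manifest.tsv"
#: zero-padding width of chunk file indices ("query_0001.fasta")
INDEX_WIDTH = 4


@dataclass(frozen=True)
class ChunkAssignment:
    """A contiguous run of records assigned to one task."""

    index: int  # 1-based task number
    first_record: int  # 0-based, inclusive
    last_record: int  # 0-based, inclusive
    total_length: int
    file_path: Path | None = None

    @property
    def n_records(self) -> int:
        return self.last_record - self.first_record + 1


@dataclass
class PartitionPlan:
    n_requested: int
    chunks: list[ChunkAssignment]
    total_length: int
    max_record_length: int

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def chunk_lengths(self) -> list[int]:
        return [c.total_length for c in self.chunks]


@dataclass(frozen=True)
class PartitionStats:
    max_length: int
    min_length: int
    mean_length: float
    max_over_mean: float
    cv: float  # coefficient of variation (population std / mean)


def chunk_file_name(index: int, width: int = INDEX_WIDTH) -> str:
    """File name of chunk ``index`` (1-based), e.g. ``query_0001.fasta``."""
    width = max(width, len(str(index)))
    return f"query_{index:0{width}d}.fasta"


def partition_lengths(
    lengths: list[int], n_chunks: int
) -> list[tuple[int, int, int]]:
    """Greedy contiguous partition of a length sequence.

    Returns ``(first_index, last_index, total_length)`` triples, 0-based
    inclusive. This is the partitioning kernel shared by :func:`plan_partition`
    and the makespan simulator.
    """
    if n_chunks < 1:
        raise ValueError(f"n_chunks must be >= 1, got {n_chunks}")
    m = len(lengths)
    if m == 0:
        raise ValueError("cannot partition an empty sequence")
    n = min(n_chunks, m)
    out: list[tuple[int, int, int]] = []
    start = 0
    remaining = sum(lengths)
    for chunks_left in range(n, 0, -1):
        if chunks_left == 1:
            out.append((start, m - 1, remaining))
            break
        thr = remaining / chunks_left
        cap = (m - start) - (chunks_left - 1)  # reserve 1 record per later chunk
        total = 0
        i = start
        while i - start < cap:
            total += lengths[i]
            i += 1
            if total >= thr:
                break
        out.append((start, i - 1, total))
        remaining -= total
        start = i
    return out


def plan_partition(qs: QuerySet, n_chunks: int) -> PartitionPlan:
    """Plan a contiguous, length-balanced partition of ``qs`` into at most
    ``n_chunks`` chunks (exactly ``min(n_chunks, len(qs))``)."""
    if len(qs) == 0:
        raise ValueError("cannot partition an empty query set")
    lengths = qs.lengths
    ranges = partition_lengths(lengths, n_chunks)
    chunks = [
        ChunkAssignment(index=k, first_record=a, last_record=b, total_length=t)
        for k, (a, b, t) in enumerate(ranges, start=1)
    ]
    return PartitionPlan(
        n_requested=n_chunks,
        chunks=chunks,
        total_length=qs.total_length,
        max_record_length=qs.max_record_length,
    )


def materialize_chunks(
    plan: PartitionPlan, qs: QuerySet, out_dir: str | Path, wrap: int = 0
) -> PartitionPlan:
    """Write one FASTA file per chunk into ``out_dir`` plus a plan manifest.

    Files are named by zero-padded 1-based chunk index so a scheduler task id
    selects its input deterministically. Records keep their original order;
    concatenating the chunk files in index order reproduces the input FASTA
    record-for-record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunks: list[ChunkAssignment] = []
    for c in plan.chunks:
        path = out_dir / chunk_file_name(c.index)
        write_fasta(qs.records[c.first_record : c.last_record + 1], path, wrap=wrap)
        chunks.append(replace(c, file_path=path))
    new_plan = PartitionPlan(
        n_requested=plan.n_requested,
        chunks=chunks,
        total_length=plan.total_length,
        max_record_length=plan.max_record_length,
    )
    write_manifest(new_plan, qs, out_dir / MANIFEST_NAME)
    return new_plan


def write_manifest(plan: PartitionPlan, qs: QuerySet, path: str | Path) -> Path:
    """Tab-separated sidecar mapping chunk index -> member query ids/lengths."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chunk\tfirst_id\tlast_id\tn_records\ttotal_length\n")
        for c in plan.chunks:
            fh.write(
                f"{c.index}\t{qs[c.first_record].id}\t{qs[c.last_record].id}"
                f"\t{c.n_records}\t{c.total_length}\n"
            )
    return path


def read_manifest(path: str | Path) -> list[dict]:
    """Parse a plan manifest back into a list of row dicts."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            idx, first_id, last_id, n_records, total = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chunk": int(idx),
                    "first_id": first_id,
                    "last_id": last_id,
                    "n_records": int(n_records),
                    "total_length": int(total),
                }
            )
    return rows


def partition_stats(plan: PartitionPlan) -> PartitionStats:
    """Balance diagnostics of a plan (max/min/mean chunk length, skew)."""
    lengths = plan.chunk_lengths
    mean = statistics.fmean(lengths)
    if len(lengths) > 1:
        sd = statistics.pstdev(lengths)
    else:
        sd = 0.0
    return PartitionStats(
        max_length=max(lengths),
        min_length=min(lengths),
        mean_length=mean,
        max_over_mean=max(lengths) / mean if mean else math.nan,
        cv=sd / mean if mean else math.nan,
    )
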