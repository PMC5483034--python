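"""Synthetic fixtures and an idealized makespan/speed-up simulator.

The generators produce reproducible query sets and subject databases from a
seed: query lengths follow a chosen law (uniform, log-normal — the typical
shape of transcript length distributions — or descending arithmetic, which
emulates assemblers that emit transcripts sorted longest-first), and each
subject can carry a planted verbatim substring of some query so the mock
engine is guaranteed hits.

The simulator prices a task as ``per_task_overhead + cost_per_residue *
chunk_length`` — run time proportional to total query length, which is the
empirical behaviour of similarity search and the entire rationale for
length-balanced (rather than record-count-balanced) splitting. Makespan is
the slowest task; speed-up is serial time over makespan. The simulator makes
no wall-clock claims: it quantifies how much of the ideal n-fold speed-up a
partitioning strategy retains under this cost model.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import SubjectDB
from .fasta_io import QuerySet, SequenceRecord
from .partition import partition_lengths

__all__ = [
    "CostModel",
    "SpeedupEstimate",
    "synth_queryset",
    "synth_subject_db",
    "simulate_makespan",
    "speedup_table",
    "write_speedup_csv",
]

_ALPHABETS = {
    "dna": "ACGT",
    "protein": "ACDEFGHIKLMNPQRSTVWY",
}

#: length-law constructors: name -> (n_params, generator)
Law = tuple[str, float, float]


@dataclass(frozen=True)
class CostModel:
    """Affine task-cost model, in seconds."""

    cost_per_residue: float = 1e-4
    per_task_overhead: float = 0.0

    def __post_init__(self) -> None:
        if self.cost_per_residue <= 0:
            raise ValueError("cost_per_residue must be > 0")
        if self.per_task_overhead < 0:
            raise ValueError("per_task_overhead must be >= 0")

    def task_time(self, chunk_length: float) -> float:
        return self.per_task_overhead + self.cost_per_residue * chunk_length


@dataclass(frozen=True)
class SpeedupEstimate:
    n_workers: int
    strategy: str
    makespan: float
    serial_time: float

    @property
    def speedup(self) -> float:
        return self.serial_time / self.makespan


def _draw_lengths(law: Law, n: int, rng: np.random.Generator) -> np.ndarray:
    name, p1, p2 = law
    if name == "uniform":
        lo, hi = int(p1), int(p2)
        if lo < 1 or hi < lo:
            raise ValueError(f"uniform law requires 1 <= lo <= hi, got {law}")
        lengths = rng.integers(lo, hi + 1, size=n)
    elif name == "lognormal":
        mu, sigma = float(p1), float(p2)
        if sigma < 0:
            raise ValueError(f"lognormal law requires sigma >= 0, got {law}")
        lengths = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    elif name == "descending":
        start, step = int(p1), int(p2)
        if start < 1 or step < 0:
            raise ValueError(f"descending law requires start >= 1, step >= 0, got {law}")
        lengths = start - step * np.arange(n, dtype=np.int64)
    else:
        raise ValueError(f"unknown length law {name!r}")
    return np.maximum(lengths, 1)


def _random_residues(length: int, alphabet: str, rng: np.random.Generator) -> str:
    letters = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    return (
        letters[rng.integers(0, letters.size, size=length)].tobytes().decode("ascii")
    )


def synth_queryset(
    n_records: int,
    law: Law = ("lognormal", 5.0, 0.8),
    alphabet: str = "dna",
    seed: int = 0,
    id_prefix: str = "synth",
) -> QuerySet:
    """Generate a reproducible random query set.

    ``law`` is ``("uniform", lo, hi)``, ``("lognormal", mu, sigma)`` (of the
    underlying normal) or ``("descending", start, step)``; lengths are
    truncated to >= 1. Ids are ``<prefix>_<i>`` (1-based). The same seed
    always yields the same records.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be one of {sorted(_ALPHABETS)}")
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(law, n_records, rng)
    chars = _ALPHABETS[alphabet]
    records = [
        SequenceRecord(
            id=f"{id_prefix}_{i + 1}",
            description="",
            residues=_random_residues(int(lengths[i]), chars, rng),
        )
        for i in range(n_records)
    ]
    return QuerySet(records, source_path="synthetic")


def synth_subject_db(
    qs: QuerySet,
    n_subjects: int,
    planted_match: int = 0,
    seed: int = 0,
    alphabet: str = "dna",
    subject_length: int = 200,
) -> SubjectDB:
    """Generate a random subject database, optionally with planted matches.

    With ``planted_match > 0``, subject *i* embeds a verbatim substring of
    that length copied from query ``i mod len(qs)``, guaranteeing the mock
    engine at least one hit of at least that length per subject.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    min_q = min(qs.lengths)
    if planted_match < 0 or (planted_match > 0 and planted_match > min_q):
        raise ValueError(
            f"planted_match must be 0 or <= the shortest query length ({min_q})"
        )
    if subject_length < max(planted_match, 1):
        raise ValueError("subject_length must cover the planted match")
    chars = _ALPHABETS.get(alphabet, alphabet)
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        residues = _random_residues(subject_length, chars, rng)
        if planted_match > 0:
            q = qs[i % len(qs)]
            q_start = int(rng.integers(0, q.length - planted_match + 1))
            fragment = q.residues[q_start : q_start + planted_match]
            s_start = int(rng.integers(0, subject_length - planted_match + 1))
            residues = (
                residues[:s_start] + fragment + residues[s_start + planted_match :]
            )
        subjects.append(SequenceRecord(id=f"subj_{i + 1}", description="", residues=residues))
    return SubjectDB(subjects)


def _count_balanced(lengths: list[int], n_workers: int) -> list[int]:
    """Chunk totals of a contiguous split into near-equal record counts."""
    groups = np.array_split(np.asarray(lengths, dtype=np.int64), min(n_workers, len(lengths)))
    return [int(g.sum()) for g in groups if g.size]


def simulate_makespan(
    lengths: list[int],
    strategy: str,
    n_workers: int,
    model: CostModel = CostModel(),
) -> SpeedupEstimate:
    """Simulate parallel completion time for one partitioning strategy.

    ``length_balanced`` partitions with the greedy length-balancing rule;
    ``count_balanced`` splits into contiguous groups of near-equal record
    counts (the naive alternative). Serial time is a single task over the
    whole input. With zero overhead, ``1 <= speedup <= n_workers`` always.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if not lengths:
        raise ValueError("lengths must be non-empty")
    if strategy == "length_balanced":
        chunk_totals = [t for _, _, t in partition_lengths(list(lengths), n_workers)]
    elif strategy == "count_balanced":
        chunk_totals = _count_balanced(list(lengths), n_workers)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    makespan = max(model.task_time(t) for t in chunk_totals)
    serial = model.task_time(sum(lengths))
    return SpeedupEstimate(
        n_workers=n_workers, strategy=strategy, makespan=makespan, serial_time=serial
    )


def speedup_table(
    lengths: list[int],
    workers: list[int],
    strategies: tuple[str, ...] = ("length_balanced", "count_balanced"),
    model: CostModel = CostModel(),
) -> list[SpeedupEstimate]:
    """Simulate every (strategy, worker-count) combination."""
    return [
        simulate_makespan(lengths, strategy, w, model)
        for strategy in strategies
        for w in workers
    ]


def write_speedup_csv(estimates: list[SpeedupEstimate], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n_workers", "strategy", "makespan", "serial_time", "speedup"])
        for e in estimates:
            writer.writerow(
                [e.n_workers, e.strategy, f"{e.makespan:.6g}", f"{e.serial_time:.6g}", f"{e.speedup:.6g}"]
            )
    return path
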