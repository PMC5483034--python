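"""Search-engine layer: BLAST+ command construction and a deterministic mock.

Two jobs live here. First, :func:`build_search_command` renders a
:class:`SearchConfig` into the exact BLAST+ argument vector a task runs, for
any of the six suite programs (blastn, blastx, blastp, tblastn, tblastx,
psiblast). Second, a fully deterministic in-process *mock* engine lets the
whole split/run/merge pipeline be exercised and byte-compared without BLAST+
installed.

The mock scores a query-subject pair by their longest common substring
(case-insensitive, exact, ungapped, forward strand only) and assigns

    bitscore = 2 * match_length
    evalue   = query_length * database_total_length * 2 ** (-bitscore)

mirroring the Karlin-Altschul structure E = m * n * 2^(-S): the expected hit
count grows with query length and database size and halves with each extra
bit of score. The crucial property is that the E-value of a hit depends only
on the query record itself and on the *whole* database — never on which
chunk the query happened to land in — so splitting a query file cannot
change any reported value. That is the invariant the merge oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fasta_io import QuerySet, SequenceRecord, read_fasta

__all__ = [
    "SUPPORTED_PROGRAMS",
    "RESERVED_OPTIONS",
    "SearchConfig",
    "SubjectDB",
    "Hit",
    "build_search_command",
    "longest_common_substring",
    "mock_search",
    "render_hits",
    "MockEngineRunner",
]

SUPPORTED_PROGRAMS = frozenset(
    {"blastn", "blastx", "blastp", "tblastn", "tblastx", "psiblast"}
)
#: options the driver owns; they may not appear in extra_options
RESERVED_OPTIONS = frozenset({"-query", "-out", "-db", "-outfmt"})

#: column names of the 12-column tabular format, in output order
TABULAR_FIELDS = (
    "query id",
    "subject id",
    "% identity",
    "alignment length",
    "mismatches",
    "gap opens",
    "q. start",
    "q. end",
    "s. start",
    "s. end",
    "evalue",
    "bit score",
)


@dataclass(frozen=True)
class SearchConfig:
    """Everything needed to render one search command."""

    program: str
    db: str
    evalue_cutoff: float = 10.0
    max_target_seqs: int = 500
    outfmt: int = 6
    extra_options: tuple[str, ...] = ()
    threads_per_task: int = 1

    def __post_init__(self) -> None:
        if self.program not in SUPPORTED_PROGRAMS:
            raise ValueError(
                f"unsupported program {self.program!r}; "
                f"expected one of {sorted(SUPPORTED_PROGRAMS)}"
            )
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.max_target_seqs < 1:
            raise ValueError("max_target_seqs must be >= 1")
        if self.outfmt not in (6, 7):
            raise ValueError(f"outfmt must be 6 or 7, got {self.outfmt}")
        if self.threads_per_task < 1:
            raise ValueError("threads_per_task must be >= 1")
        bad = RESERVED_OPTIONS.intersection(self.extra_options)
        if bad:
            raise ValueError(
                f"extra_options may not contain reserved flags: {sorted(bad)}"
            )


@dataclass
class SubjectDB:
    """The subject (database) side of a search, as plain records.

    ``total_length`` is the database size *n* entering the mock E-value; it
    is a property of the whole database and is untouched by query splitting.
    """

    subjects: list[SequenceRecord]

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SubjectDB":
        return cls(read_fasta(path).records)


@dataclass(frozen=True)
class Hit:
    """One 12-column tabular row; field order matches outfmt 6 exactly."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def to_row(self) -> str:
        return "\t".join(
            (
                self.qseqid,
                self.sseqid,
                f"{self.pident:.2f}",
                str(self.length),
                str(self.mismatch),
                str(self.gapopen),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.2e}",
                f"{self.bitscore:.1f}",
            )
        )


def build_search_command(
    cfg: SearchConfig, chunk_path: str, out_path: str
) -> list[str]:
    """Render the BLAST+ argument vector for one chunk.

    Token order is fixed (program, -query, -db, -out, -outfmt, -evalue,
    -max_target_seqs, -num_threads, then ``extra_options`` verbatim) so the
    same configuration always renders the same command.
    """
    return [
        cfg.program,
        "-query",
        str(chunk_path),
        "-db",
        cfg.db,
        "-out",
        str(out_path),
        "-outfmt",
        str(cfg.outfmt),
        "-evalue",
        str(cfg.evalue_cutoff),
        "-max_target_seqs",
        str(cfg.max_target_seqs),
        "-num_threads",
        str(cfg.threads_per_task),
        *cfg.extra_options,
    ]


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Longest exact shared substring of ``a`` and ``b``, case-insensitive.

    Returns ``(match_length, a_start, b_start)`` with 1-based starts, or
    ``(0, 0, 0)`` when no character is shared. Ties break by the smallest
    ``a_start``, then the smallest ``b_start``.
    """
    if not a or not b:
        raise ValueError("longest_common_substring requires non-empty strings")
    av = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    prev = np.zeros(bv.size + 1, dtype=np.int64)
    curr = np.zeros(bv.size + 1, dtype=np.int64)
    best = 0
    best_a_end = 0
    best_b_end = 0
    for i in range(av.size):
        # run lengths of matches ending at a[i], b[j]
        curr[1:] = np.where(bv == av[i], prev[:-1] + 1, 0)
        j = int(np.argmax(curr))
        if curr[j] > best:  # strict ">" keeps the earliest (smallest-start) tie
            best = int(curr[j])
            best_a_end = i + 1
            best_b_end = j
        prev, curr = curr, prev
    if best == 0:
        return (0, 0, 0)
    return (best, best_a_end - best + 1, best_b_end - best + 1)


def mock_search(
    queries: QuerySet,
    db: SubjectDB,
    *,
    min_match: int = 8,
    evalue_cutoff: float = 10.0,
    max_target_seqs: int = 500,
) -> list[Hit]:
    """Deterministic all-vs-all search of ``queries`` against ``db``.

    For each query-subject pair the longest common substring is found; a
    match of at least ``min_match`` residues becomes a hit (100% identity,
    no mismatches or gaps, coordinates from the match). Hits with
    ``evalue <= evalue_cutoff`` are kept; per query they are sorted by
    bitscore descending, then subject id ascending, and truncated to
    ``max_target_seqs``. Queries appear in input order.
    """
    if min_match < 1:
        raise ValueError("min_match must be >= 1")
    if max_target_seqs < 1:
        raise ValueError("max_target_seqs must be >= 1")
    n = db.total_length
    hits: list[Hit] = []
    for q in queries:
        per_query: list[Hit] = []
        for s in db.subjects:
            length, qa, sa = longest_common_substring(q.residues, s.residues)
            if length < min_match:
                continue
            bitscore = 2.0 * length
            evalue = q.length * n * 2.0 ** (-bitscore)
            if evalue > evalue_cutoff:
                continue
            per_query.append(
                Hit(
                    qseqid=q.id,
                    sseqid=s.id,
                    pident=100.0,
                    length=length,
                    mismatch=0,
                    gapopen=0,
                    qstart=qa,
                    qend=qa + length - 1,
                    sstart=sa,
                    send=sa + length - 1,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
        per_query.sort(key=lambda h: (-h.bitscore, h.sseqid))
        hits.extend(per_query[:max_target_seqs])
    return hits


def render_hits(queries: QuerySet, hits: list[Hit], outfmt: int = 6) -> str:
    """Render hits as tabular text.

    outfmt 6 is plain 12-column rows; outfmt 7 adds a per-query comment
    block (``# Query:``, ``# Fields:``, ``# <k> hits found``) for *every*
    query, including zero-hit ones, so query accounting survives merging.
    No run-level header or trailer is emitted: a file is a pure
    concatenation of per-query output, which is what makes chunk outputs
    merge into a single-run-equivalent file.
    """
    if outfmt not in (6, 7):
        raise ValueError(f"outfmt must be 6 or 7, got {outfmt}")
    by_query: dict[str, list[Hit]] = {}
    for h in hits:
        by_query.setdefault(h.qseqid, []).append(h)
    lines: list[str] = []
    if outfmt == 6:
        for q in queries:
            lines.extend(h.to_row() for h in by_query.get(q.id, ()))
    else:
        fields = ", ".join(TABULAR_FIELDS)
        for q in queries:
            qhits = by_query.get(q.id, [])
            lines.append(f"# Query: {q.header}")
            lines.append(f"# Fields: {fields}")
            lines.append(f"# {len(qhits)} hits found")
            lines.extend(h.to_row() for h in qhits)
    return "\n".join(lines) + "\n" if lines else ""


@dataclass
class MockEngineRunner:
    """In-process task runner: reads a chunk, searches ``db``, writes text.

    Satisfies the scheduler's runner protocol
    ``runner(task_id, chunk_path, out_path) -> (exit_code, stderr_excerpt)``.
    ``fail_tasks`` maps task ids to forced exit codes (fault-injection for
    tests of error logging and fault isolation).
    """

    db: SubjectDB
    min_match: int = 8
    evalue_cutoff: float = 10.0
    max_target_seqs: int = 500
    outfmt: int = 6
    fail_tasks: dict[int, int] = field(default_factory=dict)

    def __call__(
        self, task_id: int, chunk_path: Path, out_path: Path
    ) -> tuple[int, str]:
        if task_id in self.fail_tasks:
            return self.fail_tasks[task_id], f"injected failure for task {task_id}"
        try:
            queries = read_fasta(chunk_path)
            hits = mock_search(
                queries,
                self.db,
                min_match=self.min_match,
                evalue_cutoff=self.evalue_cutoff,
                max_target_seqs=self.max_target_seqs,
            )
            Path(out_path).write_text(render_hits(queries, hits, self.outfmt))
        except Exception as exc:  # failure is data for the error log
            return 1, f"{type(exc).__name__}: {exc}"
        return 0, ""
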