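"""Merging per-chunk search output into one single-run-equivalent file,
plus the per-task error log.

Because chunks are contiguous runs of the input order and every chunk output
is a pure concatenation of per-query output, concatenating chunk files in
task-index order (never completion order) reproduces the file a single
unsplit run would have written — byte for byte, E-values included. Merging
refuses to proceed when any task failed: a silently partial merge would mask
missing queries, whereas the intended workflow is to inspect the error log
and re-run just the offending chunk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .scheduler import TaskResult

__all__ = [
    "MergeError",
    "MergeReport",
    "ErrorLogEntry",
    "merge_tabular",
    "merge_results",
    "write_error_log",
    "ERROR_LOG_NAME",
]

ERROR_LOG_NAME = "dcsearch.err"


class MergeError(RuntimeError):
    """A merge could not be completed soundly."""


@dataclass(frozen=True)
class MergeReport:
    merged_path: Path
    chunks_merged: int
    data_rows: int
    comment_lines: int
    queries_seen: int  # distinct query ids in rows (outfmt 6) or comments (outfmt 7)


@dataclass(frozen=True)
class ErrorLogEntry:
    task_id: int
    chunk_file: str
    error_code: int | str  # integer exit code or "missing"
    message: str


def merge_tabular(
    outputs: list[tuple[int, Path]],
    merged_path: str | Path,
    style: int = 6,
) -> MergeReport:
    """Concatenate per-task tabular outputs, in task order, into one file.

    ``outputs`` is a list of ``(task_id, path)`` with strictly increasing
    task ids. For plain style (6) the data rows are concatenated; for
    commented style (7) every per-query comment block of every chunk appears
    exactly once — nothing is dropped or de-duplicated. A listed file that
    does not exist aborts the merge naming the task.
    """
    if style not in (6, 7):
        raise ValueError(f"style must be 6 or 7, got {style}")
    if not outputs:
        raise ValueError("no task outputs supplied")
    ids = [t for t, _ in outputs]
    if ids != sorted(ids) or len(set(ids)) != len(ids):
        raise ValueError("task ids must be strictly increasing")
    for task_id, path in outputs:
        if not Path(path).exists():
            raise MergeError(f"task {task_id}: output file missing: {path}")
    merged_path = Path(merged_path)
    merged_path.parent.mkdir(parents=True, exist_ok=True)
    data_rows = 0
    comment_lines = 0
    query_ids: set[str] = set()
    with open(merged_path, "w") as out:
        for _task_id, path in outputs:
            text = Path(path).read_text()
            out.write(text)
            for line in text.splitlines():
                if not line:
                    continue
                if line.startswith("#"):
                    comment_lines += 1
                    if style == 7 and line.startswith("# Query: "):
                        header = line[len("# Query: ") :]
                        query_ids.add(header.split(None, 1)[0])
                else:
                    data_rows += 1
                    if style == 6:
                        query_ids.add(line.split("\t", 1)[0])
    return MergeReport(
        merged_path=merged_path,
        chunks_merged=len(outputs),
        data_rows=data_rows,
        comment_lines=comment_lines,
        queries_seen=len(query_ids),
    )


def merge_results(
    results: list[TaskResult], merged_path: str | Path, style: int = 6
) -> MergeReport:
    """Merge the outputs of a completed run, refusing if any task failed."""
    failed = [r for r in results if not r.succeeded]
    if failed:
        names = ", ".join(
            f"task {r.task_id} ({_code_str(r.exit_code)})" for r in failed
        )
        raise MergeError(
            f"refusing to merge: {len(failed)} task(s) failed: {names}; "
            "inspect the error log and re-run the listed chunk files"
        )
    outputs = [(r.task_id, r.output_path) for r in results]
    return merge_tabular(outputs, merged_path, style=style)


def _code_str(code: int | None) -> str:
    return "missing" if code is None else str(code)


def write_error_log(results: list[TaskResult], path: str | Path) -> int:
    """Write the per-task error log; returns the number of entries.

    Failed tasks yield one tab-separated line each (task id, chunk file
    name, exit code or "missing", message). When every task succeeded the
    file is still created — empty — so "log exists and is empty" is the
    positive signal of a clean run.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = [
        ErrorLogEntry(
            task_id=r.task_id,
            chunk_file=Path(r.chunk_path).name,
            error_code=_code_str(r.exit_code) if r.exit_code is None else r.exit_code,
            message=r.stderr_excerpt.replace("\t", " ").replace("\n", " ").strip(),
        )
        for r in results
        if not r.succeeded
    ]
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.task_id}\t{e.chunk_file}\t{e.error_code}\t{e.message}\n")
    return len(entries)
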