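"""Task execution: a local worker pool and an SGE array-job script emitter.

One search task per chunk. On a cluster the tasks run as a Sun Grid Engine
(SGE) *array job*: one submission spawns ``task_count`` indexed tasks, and
each task reads ``$SGE_TASK_ID`` to pick its chunk file. Locally the same
command (or an in-process mock engine) runs under a bounded worker pool.
Both paths leave identical on-disk evidence — per-task output, stderr and a
sentinel ``task_<k>.exit`` file holding the decimal exit code — so result
collection and error logging do not care where the tasks ran.

Scripts are emitted, never submitted: submitting is a one-line ``qsub`` the
user runs, and failed tasks are reported for manual re-runs rather than
retried automatically.
"""

from __future__ import annotations

import shlex
import subprocess
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

from .partition import INDEX_WIDTH, PartitionPlan, chunk_file_name

__all__ = [
    "CHUNKS_DIR",
    "TASKS_DIR",
    "RESULTS_DIR",
    "EXIT_MISSING",
    "JobArray",
    "TaskResult",
    "TaskRunner",
    "CommandRunner",
    "render_sge_script",
    "run_local",
    "collect_results",
    "task_output_path",
]

CHUNKS_DIR = "chunks"
TASKS_DIR = "tasks"
RESULTS_DIR = "results"

#: placeholder tokens in a command template
CHUNK_PLACEHOLDER = "{chunk}"
OUT_PLACEHOLDER = "{out}"

#: sentinel value for a task whose exit-code file never appeared
EXIT_MISSING: None = None


class TaskRunner(Protocol):
    """Anything that can execute one task: ``(task_id, chunk, out) -> (exit_code, stderr)``."""

    def __call__(
        self, task_id: int, chunk_path: Path, out_path: Path
    ) -> tuple[int, str]: ...


@dataclass(frozen=True)
class JobArray:
    """Description of an SGE array job over the chunks of one run."""

    task_count: int
    command_template: tuple[str, ...]  # tokens; contains {chunk} and {out} once each
    work_dir: Path
    resources: tuple[str, ...] = ()  # raw directives, e.g. "-q all.q", "-pe smp 4"

    def __post_init__(self) -> None:
        if self.task_count < 1:
            raise ValueError(f"task_count must be >= 1, got {self.task_count}")
        joined = "\n".join(self.command_template)
        for ph in (CHUNK_PLACEHOLDER, OUT_PLACEHOLDER):
            if joined.count(ph) != 1:
                raise ValueError(
                    f"command_template must contain {ph!r} exactly once"
                )


@dataclass
class TaskResult:
    """Outcome of one task; ``exit_code`` is None when the sentinel is missing."""

    task_id: int
    chunk_path: Path
    output_path: Path
    exit_code: int | None
    stderr_excerpt: str = ""
    elapsed: float = 0.0  # seconds, informational only

    @property
    def succeeded(self) -> bool:
        return self.exit_code == 0 and self.output_path.exists()


def task_output_path(work_dir: str | Path, task_id: int) -> Path:
    return Path(work_dir) / TASKS_DIR / f"task_{task_id}.tab"


def render_sge_script(array: JobArray) -> str:
    """Render the POSIX shell script for an SGE array job.

    The script carries the array range directive ``#$ -t 1-<task_count>``,
    selects its chunk by zero-padding ``$SGE_TASK_ID`` into the chunk naming
    scheme, redirects per-task stdout/stderr to task-indexed files, runs the
    search command, and persists the exit code to ``tasks/task_<k>.exit``
    (SGE does not report per-task exit codes to the submitter, and the error
    log needs them post hoc). Byte-identical across calls for fixed inputs.
    """
    cmd_tokens = []
    for tok in array.command_template:
        if tok == CHUNK_PLACEHOLDER:
            cmd_tokens.append('"$CHUNK"')
        elif tok == OUT_PLACEHOLDER:
            cmd_tokens.append('"$OUT"')
        else:
            cmd_tokens.append(shlex.quote(tok))
    lines = [
        "#!/bin/sh",
        "#$ -S /bin/sh",
        "#$ -cwd",
        f"#$ -t 1-{array.task_count}",
        f"#$ -o {TASKS_DIR}/task_$TASK_ID.out",
        f"#$ -e {TASKS_DIR}/task_$TASK_ID.err",
        *[f"#$ {r}" for r in array.resources],
        "",
        f"PAD_ID=$(printf '%0{INDEX_WIDTH}d' \"$SGE_TASK_ID\")",
        f'CHUNK="{CHUNKS_DIR}/query_$PAD_ID.fasta"',
        f'OUT="{TASKS_DIR}/task_$SGE_TASK_ID.tab"',
        " ".join(cmd_tokens),
        "STATUS=$?",
        f"printf '%s\\n' \"$STATUS\" > \"{TASKS_DIR}/task_$SGE_TASK_ID.exit\"",
        'exit "$STATUS"',
    ]
    return "\n".join(lines) + "\n"


@dataclass
class CommandRunner:
    """Runs an external command per task by substituting the placeholders.

    A missing executable is reported as exit code 127 (the shell's
    command-not-found convention) with an explanatory stderr excerpt, so one
    misconfigured binary fails every task loudly instead of raising.
    """

    template: tuple[str, ...]
    timeout: float | None = None

    def __call__(
        self, task_id: int, chunk_path: Path, out_path: Path
    ) -> tuple[int, str]:
        argv = [
            tok.replace(CHUNK_PLACEHOLDER, str(chunk_path)).replace(
                OUT_PLACEHOLDER, str(out_path)
            )
            for tok in self.template
        ]
        try:
            proc = subprocess.run(
                argv, capture_output=True, text=True, timeout=self.timeout
            )
        except FileNotFoundError:
            return 127, f"runner not found: {argv[0]}"
        except subprocess.TimeoutExpired:
            return 124, f"task {task_id} timed out after {self.timeout}s"
        return proc.returncode, proc.stderr[-2000:]


def _write_sentinels(tasks_dir: Path, task_id: int, code: int, stderr: str) -> None:
    (tasks_dir / f"task_{task_id}.exit").write_text(f"{code}\n")
    (tasks_dir / f"task_{task_id}.err").write_text(stderr)


def run_local(
    plan: PartitionPlan,
    runner: TaskRunner,
    workers: int,
    work_dir: str | Path,
) -> list[TaskResult]:
    """Execute every chunk task exactly once with at most ``workers`` concurrent.

    Results come back ordered by task id regardless of completion order, and
    a failing task never aborts the others. The same sentinel files the SGE
    script would write are produced, so :func:`collect_results` applies to
    local runs too.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    work_dir = Path(work_dir)
    tasks_dir = work_dir / TASKS_DIR
    tasks_dir.mkdir(parents=True, exist_ok=True)
    for c in plan.chunks:
        if c.file_path is None:
            raise ValueError("plan has unmaterialized chunks; call materialize_chunks")

    def _one(chunk) -> TaskResult:
        out_path = task_output_path(work_dir, chunk.index)
        t0 = time.perf_counter()
        try:
            code, stderr = runner(chunk.index, chunk.file_path, out_path)
        except Exception as exc:  # a crashing runner is a failed task, not a crash
            code, stderr = 1, f"runner raised {type(exc).__name__}: {exc}"
        elapsed = time.perf_counter() - t0
        _write_sentinels(tasks_dir, chunk.index, code, stderr)
        return TaskResult(
            task_id=chunk.index,
            chunk_path=chunk.file_path,
            output_path=out_path,
            exit_code=code,
            stderr_excerpt=stderr,
            elapsed=elapsed,
        )

    with ThreadPoolExecutor(max_workers=workers) as pool:
        results = list(pool.map(_one, plan.chunks))
    return sorted(results, key=lambda r: r.task_id)


def collect_results(work_dir: str | Path, task_count: int) -> list[TaskResult]:
    """Re-attach to a finished (or partial) run from its sentinel files.

    One :class:`TaskResult` per expected task; a missing sentinel marks the
    task failed with ``exit_code=None`` ("missing") — missingness is data,
    not an exception.
    """
    if task_count < 1:
        raise ValueError(f"task_count must be >= 1, got {task_count}")
    work_dir = Path(work_dir)
    tasks_dir = work_dir / TASKS_DIR
    chunks_dir = work_dir / CHUNKS_DIR
    results = []
    for k in range(1, task_count + 1):
        sentinel = tasks_dir / f"task_{k}.exit"
        err_file = tasks_dir / f"task_{k}.err"
        stderr = err_file.read_text()[-2000:] if err_file.exists() else ""
        if sentinel.exists():
            text = sentinel.read_text().strip()
            try:
                code: int | None = int(text)
            except ValueError:
                code = None
                stderr = stderr or f"unparseable exit sentinel: {text!r}"
        else:
            code = EXIT_MISSING
            stderr = stderr or "exit sentinel missing (task never completed?)"
        results.append(
            TaskResult(
                task_id=k,
                chunk_path=chunks_dir / chunk_file_name(k),
                output_path=task_output_path(work_dir, k),
                exit_code=code,
                stderr_excerpt=stderr,
            )
        )
    return results
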