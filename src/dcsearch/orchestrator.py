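"""End-to-end pipeline: split -> (local run | SGE script) -> merge -> error log.

A run lives in a fixed work-directory tree::

    work_dir/
      chunks/        query_0001.fasta ... + manifest.tsv
      tasks/         task_<k>.tab/.out/.err/.exit
      results/       merged.tab
      array_job.sh   (sge-script mode)
      run.json       run metadata, used by `collect` to re-attach
      dcsearch.err   per-task error log
      run.log        mirrored structured log

Local mode executes the whole workflow in one call. In sge-script mode the
pipeline splits the query, renders the array-job script and stops; the user
submits with ``qsub array_job.sh`` and later resumes with
:func:`collect_run`, which gathers sentinel files, writes the error log and
merges if everything succeeded.
"""

from __future__ import annotations

import configparser
import json
import logging
import shlex
from dataclasses import dataclass
from pathlib import Path

from . import engine, merge_report, partition, scheduler
from .engine import MockEngineRunner, SearchConfig, SubjectDB
from .fasta_io import read_fasta
from .merge_report import ERROR_LOG_NAME, MergeError
from .scheduler import CHUNKS_DIR, RESULTS_DIR, CommandRunner, JobArray

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineError",
    "PipelineSettings",
    "RunReport",
    "load_config",
    "run_pipeline",
    "collect_run",
    "MERGED_NAME",
    "SCRIPT_NAME",
    "RUN_META_NAME",
]

MERGED_NAME = "merged.tab"
SCRIPT_NAME = "array_job.sh"
RUN_META_NAME = "run.json"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineSettings:
    """Resolved configuration of one run (INI file merged with CLI flags)."""

    query: Path
    work_dir: Path
    n_chunks: int
    search: SearchConfig
    mode: str = "local"  # local | sge-script
    engine: str = "mock"  # mock | blast
    workers: int = 1
    min_match: int = 8  # mock engine only
    sge_resources: tuple[str, ...] = ()


@dataclass
class RunReport:
    """What a run produced; ``merged_path`` is set only on full success."""

    input_path: Path
    work_dir: Path
    n_requested: int
    chunks_produced: int
    tasks_succeeded: int
    tasks_failed: int
    merged_path: Path | None
    error_log_path: Path | None
    manifest_path: Path
    script_path: Path | None = None

    @property
    def ok(self) -> bool:
        return self.tasks_failed == 0 and self.merged_path is not None

    def summary(self) -> str:
        lines = [
            f"query:      {self.input_path}",
            f"work dir:   {self.work_dir}",
            f"chunks:     {self.chunks_produced} (requested {self.n_requested})",
        ]
        if self.script_path is not None:
            lines.append(f"SGE script: {self.script_path}  (submit with: qsub {self.script_path.name})")
        else:
            lines.append(f"tasks:      {self.tasks_succeeded} succeeded, {self.tasks_failed} failed")
            lines.append(f"merged:     {self.merged_path if self.merged_path else '(not merged: failures)'}")
            lines.append(f"error log:  {self.error_log_path}")
        return "\n".join(lines)


def load_config(
    ini_path: str | Path | None, overrides: dict | None = None
) -> PipelineSettings:
    """Build settings from an INI file plus CLI-style overrides.

    The INI dialect has three sections: ``[dcsearch]`` (query, work_dir,
    n_chunks, mode, engine, workers, min_match), ``[blast]`` (program, db,
    evalue, max_target_seqs, outfmt, threads, extra) and ``[sge]`` (one
    ``directives`` value, one scheduler directive per line). Any override
    with a non-None value wins over the file.
    """
    cp = configparser.ConfigParser()
    if ini_path is not None:
        read = cp.read(str(ini_path))
        if not read:
            raise PipelineError(f"config: cannot read INI file {ini_path}")
    ov = {k: v for k, v in (overrides or {}).items() if v is not None}

    def get(section: str, key: str, fallback=None):
        if key in ov:
            return ov[key]
        return cp.get(section, key, fallback=fallback)

    extra_raw = get("blast", "extra", fallback="")
    extra = tuple(shlex.split(extra_raw)) if isinstance(extra_raw, str) else tuple(extra_raw)
    search = SearchConfig(
        program=get("blast", "program", fallback="blastn"),
        db=str(get("blast", "db", fallback="")),
        evalue_cutoff=float(get("blast", "evalue", fallback=10.0)),
        max_target_seqs=int(get("blast", "max_target_seqs", fallback=500)),
        outfmt=int(get("blast", "outfmt", fallback=6)),
        extra_options=extra,
        threads_per_task=int(get("blast", "threads", fallback=1)),
    )
    directives_raw = get("sge", "directives", fallback="")
    directives = tuple(
        line.strip() for line in str(directives_raw).splitlines() if line.strip()
    )
    query = get("dcsearch", "query")
    if query is None:
        raise PipelineError("config: a query FASTA path is required")
    return PipelineSettings(
        query=Path(query),
        work_dir=Path(get("dcsearch", "work_dir", fallback="dcsearch_run")),
        n_chunks=int(get("dcsearch", "n_chunks", fallback=1)),
        search=search,
        mode=str(get("dcsearch", "mode", fallback="local")),
        engine=str(get("dcsearch", "engine", fallback="mock")),
        workers=int(get("dcsearch", "workers", fallback=1)),
        min_match=int(get("dcsearch", "min_match", fallback=8)),
        sge_resources=directives,
    )


def _setup_run_logging(work_dir: Path) -> None:
    """Mirror pipeline logging to work_dir/run.log (idempotent per dir)."""
    root = logging.getLogger("dcsearch")
    log_path = work_dir / "run.log"
    for h in root.handlers:
        if isinstance(h, logging.FileHandler) and Path(h.baseFilename) == log_path:
            return
    handler = logging.FileHandler(log_path)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root.addHandler(handler)
    root.setLevel(logging.INFO)


def _resolved_db(settings: PipelineSettings) -> str:
    # the array script runs with cwd=work_dir; a db given as an existing
    # relative path must survive that change of directory
    db = settings.search.db
    if db and Path(db).exists():
        return str(Path(db).resolve())
    return db


def _command_template(settings: PipelineSettings) -> tuple[str, ...]:
    """The per-task command, with {chunk}/{out} placeholders."""
    if settings.engine == "blast":
        from dataclasses import replace as _replace

        cfg = _replace(settings.search, db=_resolved_db(settings))
        return tuple(
            engine.build_search_command(
                cfg, scheduler.CHUNK_PLACEHOLDER, scheduler.OUT_PLACEHOLDER
            )
        )
    # mock engine as an external command, so the SGE script stays runnable
    return (
        "dcsearch",
        "mock-task",
        "--db",
        _resolved_db(settings),
        "--outfmt",
        str(settings.search.outfmt),
        "--evalue",
        str(settings.search.evalue_cutoff),
        "--max-target-seqs",
        str(settings.search.max_target_seqs),
        "--min-match",
        str(settings.min_match),
        "--query",
        scheduler.CHUNK_PLACEHOLDER,
        "--out",
        scheduler.OUT_PLACEHOLDER,
    )


def _make_runner(settings: PipelineSettings):
    if settings.engine == "mock":
        if not settings.search.db:
            raise PipelineError("run: the mock engine needs a subject FASTA as db")
        try:
            db = SubjectDB.from_fasta(settings.search.db)
        except OSError as exc:
            raise PipelineError(f"run: cannot read mock db: {exc}") from exc
        return MockEngineRunner(
            db=db,
            min_match=settings.min_match,
            evalue_cutoff=settings.search.evalue_cutoff,
            max_target_seqs=settings.search.max_target_seqs,
            outfmt=settings.search.outfmt,
        )
    if settings.engine == "blast":
        return CommandRunner(template=_command_template(settings))
    raise PipelineError(f"run: unknown engine {settings.engine!r}")


def run_pipeline(settings: PipelineSettings, runner=None) -> RunReport:
    """Execute the workflow: split, then run-and-merge (local) or emit the
    array script (sge-script). ``runner`` overrides the engine-derived task
    runner (used for fault injection in tests)."""
    work_dir = settings.work_dir
    work_dir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(work_dir)
    logger.info("run: query=%s n_chunks=%d mode=%s engine=%s",
                settings.query, settings.n_chunks, settings.mode, settings.engine)

    try:
        qs = read_fasta(settings.query)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"split: {exc}") from exc

    plan = partition.plan_partition(qs, settings.n_chunks)
    chunks_dir = work_dir / CHUNKS_DIR
    plan = partition.materialize_chunks(plan, qs, chunks_dir)
    manifest_path = chunks_dir / partition.MANIFEST_NAME
    stats = partition.partition_stats(plan)
    logger.info(
        "split: %d chunks, max/mean=%.3f cv=%.3f", plan.n_chunks,
        stats.max_over_mean, stats.cv,
    )

    meta = {
        "query": str(settings.query),
        "n_requested": settings.n_chunks,
        "task_count": plan.n_chunks,
        "engine": settings.engine,
        "outfmt": settings.search.outfmt,
        "db": settings.search.db,
        "mode": settings.mode,
    }
    (work_dir / RUN_META_NAME).write_text(json.dumps(meta, indent=2) + "\n")

    if settings.mode == "sge-script":
        array = JobArray(
            task_count=plan.n_chunks,
            command_template=_command_template(settings),
            work_dir=work_dir,
            resources=settings.sge_resources,
        )
        script_path = work_dir / SCRIPT_NAME
        script_path.write_text(scheduler.render_sge_script(array))
        (work_dir / scheduler.TASKS_DIR).mkdir(exist_ok=True)
        logger.info("sge-script: wrote %s (submit with qsub)", script_path)
        return RunReport(
            input_path=settings.query,
            work_dir=work_dir,
            n_requested=settings.n_chunks,
            chunks_produced=plan.n_chunks,
            tasks_succeeded=0,
            tasks_failed=0,
            merged_path=None,
            error_log_path=None,
            manifest_path=manifest_path,
            script_path=script_path,
        )
    if settings.mode != "local":
        raise PipelineError(f"run: unknown mode {settings.mode!r}")

    if runner is None:
        runner = _make_runner(settings)
    results = scheduler.run_local(plan, runner, settings.workers, work_dir)
    return _finish(settings.query, work_dir, settings.n_chunks, plan.n_chunks,
                   results, settings.search.outfmt, manifest_path)


def _finish(query, work_dir, n_requested, task_count, results, outfmt, manifest_path):
    error_log_path = work_dir / ERROR_LOG_NAME
    n_err = merge_report.write_error_log(results, error_log_path)
    n_ok = sum(1 for r in results if r.succeeded)
    merged_path = None
    if n_err == 0:
        merged_path = work_dir / RESULTS_DIR / MERGED_NAME
        merge_report.merge_results(results, merged_path, style=outfmt)
        logger.info("merge: %d task outputs -> %s", task_count, merged_path)
    else:
        logger.warning("merge skipped: %d failed task(s), see %s", n_err, error_log_path)
    return RunReport(
        input_path=Path(query),
        work_dir=Path(work_dir),
        n_requested=n_requested,
        chunks_produced=task_count,
        tasks_succeeded=n_ok,
        tasks_failed=len(results) - n_ok,
        merged_path=merged_path,
        error_log_path=error_log_path,
        manifest_path=manifest_path,
    )


def collect_run(work_dir: str | Path) -> RunReport:
    """Re-attach to a finished array run: gather sentinels, write the error
    log, and merge when every task succeeded."""
    work_dir = Path(work_dir)
    meta_path = work_dir / RUN_META_NAME
    if not meta_path.exists():
        raise PipelineError(f"collect: no {RUN_META_NAME} in {work_dir}")
    meta = json.loads(meta_path.read_text())
    _setup_run_logging(work_dir)
    results = scheduler.collect_results(work_dir, meta["task_count"])
    return _finish(
        meta["query"], work_dir, meta["n_requested"], meta["task_count"],
        results, meta["outfmt"], work_dir / CHUNKS_DIR / partition.MANIFEST_NAME,
    )
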