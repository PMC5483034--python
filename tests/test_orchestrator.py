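import os
import subprocess
from pathlib import Path

import pytest
from click.testing import CliRunner

from dcsearch import (
    MockEngineRunner,
    PipelineError,
    SearchConfig,
    SubjectDB,
    collect_run,
    load_config,
    mock_search,
    read_fasta,
    render_hits,
    run_pipeline,
    synth_queryset,
    synth_subject_db,
    write_fasta,
)
from dcsearch.cli import main as cli_main
from dcsearch.orchestrator import SCRIPT_NAME, PipelineSettings


@pytest.fixture
def fixture_files(tmp_path):
    qs = synth_queryset(100, law=("lognormal", 4.3, 0.7), seed=51)
    db = synth_subject_db(qs, 12, planted_match=10, seed=52)
    query_path = tmp_path / "query.fasta"
    db_path = tmp_path / "db.fasta"
    write_fasta(qs.records, query_path)
    write_fasta(db.subjects, db_path)
    return qs, db, query_path, db_path, tmp_path


def settings_for(query_path, db_path, work_dir, **kw):
    cfg = SearchConfig(
        program="blastn", db=str(db_path), evalue_cutoff=1.0,
        outfmt=kw.pop("outfmt", 6),
    )
    return PipelineSettings(
        query=Path(query_path), work_dir=Path(work_dir), search=cfg,
        n_chunks=kw.pop("n_chunks", 4), **kw,
    )


class TestLocalMode:
    def test_full_run_matches_unsplit_oracle(self, fixture_files):
        qs, db, query_path, db_path, tmp = fixture_files
        s = settings_for(query_path, db_path, tmp / "run", workers=4)
        report = run_pipeline(s)
        assert report.ok
        assert (report.tasks_succeeded, report.tasks_failed) == (4, 0)
        single = render_hits(qs, mock_search(qs, db, evalue_cutoff=1.0), 6)
        assert report.merged_path.read_text() == single
        assert report.error_log_path.read_text() == ""
        assert report.manifest_path.exists()

    def test_two_runs_byte_identical(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        texts = []
        for name in ("a", "b"):
            s = settings_for(query_path, db_path, tmp / name, workers=2)
            texts.append(run_pipeline(s).merged_path.read_text())
        assert texts[0] == texts[1]

    def test_failed_task_blocks_merge_and_fills_log(self, fixture_files):
        qs, db, query_path, db_path, tmp = fixture_files
        s = settings_for(query_path, db_path, tmp / "fail")
        runner = MockEngineRunner(db=db, evalue_cutoff=1.0, fail_tasks={3: 2})
        report = run_pipeline(s, runner=runner)
        assert not report.ok
        assert report.merged_path is None
        assert report.tasks_failed == 1
        (line,) = report.error_log_path.read_text().splitlines()
        assert line.split("\t")[:3] == ["3", "query_0003.fasta", "2"]

    def test_remerge_is_idempotent(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        s = settings_for(query_path, db_path, tmp / "run")
        first = run_pipeline(s).merged_path.read_text()
        again = collect_run(tmp / "run")
        assert again.merged_path.read_text() == first

    def test_unreadable_query_names_stage(self, fixture_files, tmp_path):
        _, _, _, db_path, tmp = fixture_files
        s = settings_for(tmp_path / "nope.fasta", db_path, tmp / "x")
        with pytest.raises(PipelineError, match="split"):
            run_pipeline(s)


class TestSgeScriptMode:
    def test_artifacts_written_and_no_merge(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        s = settings_for(query_path, db_path, tmp / "sge", mode="sge-script",
                         sge_resources=("-q all.q",))
        report = run_pipeline(s)
        assert report.script_path == tmp / "sge" / SCRIPT_NAME
        script = report.script_path.read_text()
        assert "#$ -t 1-4" in script and "$SGE_TASK_ID" in script
        assert "#$ -q all.q" in script
        assert len(list((tmp / "sge" / "chunks").glob("query_*.fasta"))) == 4
        assert report.merged_path is None

    def test_script_runs_and_collect_merges(self, fixture_files):
        """Execute the emitted script once per task id, as the scheduler
        would, then collect: the merge equals the unsplit run."""
        qs, db, query_path, db_path, tmp = fixture_files
        s = settings_for(query_path, db_path, tmp / "sge2", mode="sge-script")
        report = run_pipeline(s)
        for k in range(1, 5):
            env = dict(os.environ, SGE_TASK_ID=str(k))
            proc = subprocess.run(
                ["sh", SCRIPT_NAME], cwd=tmp / "sge2", env=env,
                capture_output=True, text=True,
            )
            assert proc.returncode == 0, proc.stderr
        collected = collect_run(tmp / "sge2")
        assert collected.ok
        single = render_hits(qs, mock_search(qs, db, evalue_cutoff=1.0), 6)
        assert collected.merged_path.read_text() == single


class TestConfig:
    def test_ini_round_trip(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        ini = tmp / "run.ini"
        ini.write_text(
            "[dcsearch]\n"
            f"query = {query_path}\n"
            f"work_dir = {tmp / 'ini_run'}\n"
            "n_chunks = 3\n"
            "workers = 2\n"
            "[blast]\n"
            "program = blastx\n"
            f"db = {db_path}\n"
            "evalue = 1e-10\n"
            "max_target_seqs = 1\n"
            "outfmt = 7\n"
            "extra = -word_size 11\n"
            "[sge]\n"
            "directives = -q all.q\n\t-pe smp 4\n"
        )
        s = load_config(ini)
        assert s.n_chunks == 3 and s.workers == 2
        assert s.search.program == "blastx"
        assert s.search.evalue_cutoff == 1e-10
        assert s.search.max_target_seqs == 1
        assert s.search.extra_options == ("-word_size", "11")
        assert s.sge_resources == ("-q all.q", "-pe smp 4")

    def test_cli_flags_override_file(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        ini = tmp / "run.ini"
        ini.write_text(f"[dcsearch]\nquery = {query_path}\nn_chunks = 3\n[blast]\ndb = {db_path}\n")
        s = load_config(ini, {"n_chunks": 8, "program": None})
        assert s.n_chunks == 8

    def test_missing_query_rejected(self):
        with pytest.raises(PipelineError, match="query"):
            load_config(None, {"work_dir": "w"})


class TestCli:
    def test_run_and_exit_codes(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "run", "--query", str(query_path), "--chunks", "4",
            "--db", str(db_path), "--work-dir", str(tmp / "cli_run"),
            "--workers", "2", "--evalue", "1.0",
        ])
        assert result.exit_code == 0, result.output
        assert "4 succeeded" in result.output
        assert (tmp / "cli_run" / "results" / "merged.tab").exists()

    def test_run_sge_script_mode(self, fixture_files):
        _, _, query_path, db_path, tmp = fixture_files
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "run", "--query", str(query_path), "--chunks", "2",
            "--db", str(db_path), "--work-dir", str(tmp / "cli_sge"),
            "--mode", "sge-script",
        ])
        assert result.exit_code == 0, result.output
        assert (tmp / "cli_sge" / SCRIPT_NAME).exists()

    def test_simulate_prints_table(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "simulate", "--law", "descending(1000,1)", "--n-records", "256",
            "--workers", "1,8", "--out", str(tmp_path / "s.csv"),
        ])
        assert result.exit_code == 0, result.output
        assert "length_balanced" in result.output
        assert (tmp_path / "s.csv").exists()
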