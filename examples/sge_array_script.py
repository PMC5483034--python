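"""Emit the SGE array-job script for a chunked search.

Each array task reads $SGE_TASK_ID, zero-pads it into the chunk file name,
runs the search command on that chunk, and persists its exit code to a
sentinel file that `dcsearch collect` (or collect_results) reads later.
"""

from pathlib import Path

from dcsearch import JobArray, SearchConfig, build_search_command, render_sge_script

cfg = SearchConfig(
    program="blastx",
    db="/data/db/swissprot",
    evalue_cutoff=1e-10,
    max_target_seqs=1,
    outfmt=6,
    threads_per_task=1,
)
template = tuple(build_search_command(cfg, "{chunk}", "{out}"))

array = JobArray(
    task_count=16,
    command_template=template,
    work_dir=Path("run"),
    resources=("-q all.q", "-pe smp 1"),
)
script = render_sge_script(array)
print(script)
print("# Submit from the work directory with: qsub array_job.sh")
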