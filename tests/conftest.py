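import pytest

from dcsearch import synth_queryset, synth_subject_db


@pytest.fixture
def small_queryset():
    """A reproducible 20-record DNA query set with log-normal lengths."""
    return synth_queryset(20, law=("lognormal", 4.0, 0.6), seed=11)


@pytest.fixture
def planted_pair():
    """(QuerySet, SubjectDB) where every subject embeds a 12-residue query
    substring, so the mock engine is guaranteed hits."""
    qs = synth_queryset(30, law=("uniform", 60, 150), seed=21)
    db = synth_subject_db(qs, 10, planted_match=12, seed=22, subject_length=180)
    return qs, db
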