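import pytest
from hypothesis import given, settings, strategies as st

from dcsearch import (
    QuerySet,
    SearchConfig,
    SequenceRecord,
    SubjectDB,
    build_search_command,
    longest_common_substring,
    mock_search,
    plan_partition,
    render_hits,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=30)


def brute_force_lcs(a, b):
    """Independent oracle: enumerate every substring of `a` longest-first and
    scan `b` for it; ties resolved by smallest a_start then b_start."""
    a_u, b_u = a.upper(), b.upper()
    for length in range(min(len(a_u), len(b_u)), 0, -1):
        best = None
        for i in range(len(a_u) - length + 1):
            j = b_u.find(a_u[i : i + length])
            if j != -1 and best is None:
                best = (length, i + 1, j + 1)
        if best:
            return best
    return (0, 0, 0)


class TestCommandConstruction:
    def test_token_order_and_values(self):
        cfg = SearchConfig(
            program="blastx", db="swissprot", evalue_cutoff=1e-10, max_target_seqs=1
        )
        tokens = build_search_command(cfg, "chunks/query_0001.fasta", "tasks/task_1.tab")
        joined = " ".join(tokens)
        assert tokens[0] == "blastx"
        assert "-evalue 1e-10" in joined
        assert "-max_target_seqs 1" in joined
        assert "-query chunks/query_0001.fasta" in joined
        assert "-db swissprot" in joined

    def test_extra_options_appended_last_in_order(self):
        cfg = SearchConfig(
            program="blastn", db="nt", extra_options=("-word_size", "11", "-dust", "no")
        )
        tokens = build_search_command(cfg, "q.fa", "o.tab")
        assert tokens[-4:] == ["-word_size", "11", "-dust", "no"]

    def test_reserved_extra_option_rejected(self):
        with pytest.raises(ValueError, match="reserved"):
            SearchConfig(program="blastn", db="nt", extra_options=("-query", "x"))

    def test_unsupported_program_rejected(self):
        with pytest.raises(ValueError, match="unsupported program"):
            SearchConfig(program="megablast", db="nt")

    def test_deterministic(self):
        cfg = SearchConfig(program="tblastn", db="db", threads_per_task=4)
        assert build_search_command(cfg, "a", "b") == build_search_command(cfg, "a", "b")


class TestLongestCommonSubstring:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (4, 1, 1)),
            ("TTACGTAA", "GGACGTCC", (4, 3, 3)),
            ("AAAA", "CCCC", (0, 0, 0)),
            ("acgt", "ACGT", (4, 1, 1)),  # case-insensitive
        ],
    )
    def test_known_cases(self, a, b, expected):
        assert longest_common_substring(a, b) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            longest_common_substring("", "ACGT")

    @settings(max_examples=200, deadline=None)
    @given(a=DNA, b=DNA)
    def test_matches_brute_force(self, a, b):
        assert longest_common_substring(a, b) == brute_force_lcs(a, b)


class TestMockSearch:
    def test_closed_form_evalue(self):
        """Identical 20-mer query/subject in a 100-residue database:
        bitscore 40, evalue = 20*100*2^-40 ~ 1.82e-9."""
        qs = QuerySet([SequenceRecord("q", "", "A" * 20)])
        db = SubjectDB(
            [SequenceRecord("s1", "", "A" * 20), SequenceRecord("s2", "", "C" * 80)]
        )
        hits = mock_search(qs, db, evalue_cutoff=1e-3)
        assert len(hits) == 1
        h = hits[0]
        assert (h.length, h.bitscore) == (20, 40.0)
        assert h.evalue == pytest.approx(20 * 100 * 2.0**-40)
        assert f"{h.evalue:.2e}" == "1.82e-09"
        assert (h.qstart, h.qend, h.sstart, h.send) == (1, 20, 1, 20)

    def test_short_matches_dropped(self):
        qs = QuerySet([SequenceRecord("q", "", "ACGTACG")])
        db = SubjectDB([SequenceRecord("s", "", "ACGTACG")])
        assert mock_search(qs, db, min_match=8) == []
        assert len(mock_search(qs, db, min_match=7)) == 1

    def test_evalue_independent_of_chunk_membership(self, planted_pair):
        """The same query produces byte-identical rows whether searched in the
        full set or inside any chunk, because the db is untouched."""
        qs, db = planted_pair
        full_hits = mock_search(qs, db)
        for n_chunks in (2, 3, 8):
            plan = plan_partition(qs, n_chunks)
            rebuilt = []
            for c in plan.chunks:
                sub = QuerySet(qs.records[c.first_record : c.last_record + 1])
                rebuilt.extend(h.to_row() for h in mock_search(sub, db))
            assert rebuilt == [h.to_row() for h in full_hits]

    def test_cutoff_monotonicity(self, planted_pair):
        """Raising the E-value cutoff never removes a hit; lowering
        max_target_seqs never adds one."""
        qs, db = planted_pair
        loose = {h.to_row() for h in mock_search(qs, db, evalue_cutoff=10.0)}
        strict = {h.to_row() for h in mock_search(qs, db, evalue_cutoff=1e-6)}
        assert strict <= loose
        many = {h.to_row() for h in mock_search(qs, db, max_target_seqs=50)}
        few = {h.to_row() for h in mock_search(qs, db, max_target_seqs=1)}
        assert few <= many

    def test_hits_sorted_per_query(self, planted_pair):
        qs, db = planted_pair
        hits = mock_search(qs, db)
        by_query = {}
        for h in hits:
            by_query.setdefault(h.qseqid, []).append(h)
        for qhits in by_query.values():
            keys = [(-h.bitscore, h.sseqid) for h in qhits]
            assert keys == sorted(keys)


class TestRendering:
    def test_outfmt6_row_has_12_columns(self, planted_pair):
        qs, db = planted_pair
        text = render_hits(qs, mock_search(qs, db), 6)
        rows = [l for l in text.splitlines() if l]
        assert rows and all(len(r.split("\t")) == 12 for r in rows)

    def test_outfmt7_blocks_cover_every_query(self, planted_pair):
        """Commented style has exactly one '# Query:' block per input record,
        zero-hit queries included, each with a Fields and a count line."""
        qs, db = planted_pair
        text = render_hits(qs, mock_search(qs, db, evalue_cutoff=1e-30), 7)
        lines = text.splitlines()
        query_lines = [l for l in lines if l.startswith("# Query: ")]
        assert len(query_lines) == len(qs)
        assert [l[len("# Query: "):] for l in query_lines] == [r.header for r in qs]
        assert sum(1 for l in lines if l.startswith("# Fields:")) == len(qs)
        assert any(l == "# 0 hits found" for l in lines)

    def test_outfmt7_hit_counts_match_rows(self, planted_pair):
        qs, db = planted_pair
        text = render_hits(qs, mock_search(qs, db), 7)
        declared = sum(
            int(l.split()[1]) for l in text.splitlines() if l.endswith("hits found")
        )
        rows = sum(1 for l in text.splitlines() if l and not l.startswith("#"))
        assert declared == rows
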