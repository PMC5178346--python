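"""Tabular hit parsing, species-level filtering, and chunked search."""

import random

import pytest

from envotag import fixtures
from envotag.errors import InputError, ParseError
from envotag.search import (
    FilterParams,
    Hit,
    extract_record_id,
    filter_hits,
    parse_tabular,
    run_search,
)
from envotag.sequence_io import parse_and_rename


def _hit(q="C1", s="S1", pident=98.5, aln=120, evalue=1e-20, bits=200.0, qlen=120):
    return Hit(q, s, pident, aln, evalue, bits, qlen)


def _row(q, s, pident, aln, evalue, bits):
    return f"{q}\t{s}\t{pident}\t{aln}\t1\t0\t1\t{aln}\t1\t{aln}\t{evalue}\t{bits}"


class TestParseTabular:
    def test_parses_rows_and_joins_query_length(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "\n".join(_row("C1", f"S{i}", 99.0, 120, 1e-30, 200) for i in range(3)) + "\n"
        )
        hits = parse_tabular(path, {"C1": 120})
        assert len(hits) == 3 and hits[0].query_length == 120

    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert parse_tabular(path, {}) == []

    def test_identity_over_100_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_row("C1", "S1", 101.0, 120, 1e-30, 200) + "\n")
        with pytest.raises(ParseError, match="identity"):
            parse_tabular(path, {"C1": 120})

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("C1\tS1\t99.0\n")
        with pytest.raises(ParseError, match="line 1"):
            parse_tabular(path, {"C1": 120})

    def test_unknown_query_length_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_row("C9", "S1", 99.0, 120, 1e-30, 200) + "\n")
        with pytest.raises(InputError, match="C9"):
            parse_tabular(path, {"C1": 120})


class TestFilterHits:
    def test_defaults(self):
        assert FilterParams() == FilterParams(1e-4, 0.97, 0.97, 10)

    @pytest.mark.parametrize(
        "hit, kept",
        [
            (_hit(evalue=1e-5, pident=98.0, aln=99, qlen=100), True),
            (_hit(evalue=1e-2, pident=99.0, aln=100, qlen=100), False),  # e-value
            (_hit(evalue=1e-5, pident=96.0, aln=100, qlen=100), False),  # identity
            (_hit(evalue=1e-5, pident=99.0, aln=90, qlen=100), False),   # coverage
        ],
    )
    def test_threshold_screen(self, hit, kept):
        table = filter_hits([hit])
        assert (hit.query_id in table) == kept

    def test_max_targets_keeps_smallest_evalues(self):
        hits = [_hit(s=f"S{i:02d}", evalue=1e-30 * 10**i) for i in range(12)]
        random.Random(0).shuffle(hits)
        table = filter_hits(hits)
        # oracle: full sort, take 10 best
        expect = [h.subject_id for h in sorted(hits, key=lambda h: h.evalue)[:10]]
        assert table["C1"] == expect

    def test_tie_break_bitscore_then_subject(self):
        hits = [
            _hit(s="B", evalue=1e-20, bits=100.0),
            _hit(s="A", evalue=1e-20, bits=100.0),
            _hit(s="Z", evalue=1e-20, bits=300.0),
        ]
        assert filter_hits(hits)["C1"] == ["Z", "A", "B"]

    def test_duplicate_subjects_collapse(self):
        hits = [_hit(s="S1", evalue=1e-30), _hit(s="S1", evalue=1e-20)]
        assert filter_hits(hits)["C1"] == ["S1"]

    def test_idempotent_and_monotone(self):
        rng = random.Random(7)
        hits = [
            _hit(
                q=f"C{rng.randint(1, 3)}",
                s=f"S{rng.randint(0, 30)}",
                pident=rng.uniform(90, 100),
                aln=rng.randint(100, 120),
                evalue=10.0 ** rng.uniform(-40, 0),
            )
            for _ in range(100)
        ]
        tight = filter_hits(hits, FilterParams())
        loose = filter_hits(hits, FilterParams(1e-2, 0.9, 0.9, 10))
        for q, subs in tight.items():
            assert len(subs) <= 10
            assert set(subs) <= set(loose.get(q, []) ) or len(loose[q]) == 10
        # loosening never shrinks the retained set size per query
        for q in tight:
            assert len(loose.get(q, [])) >= min(len(tight[q]), 10)


class TestExtractRecordId:
    @pytest.mark.parametrize(
        "subject, expected",
        [
            ("gi|123456|gb|AY123456.1|", "123456"),
            ("AY123456.1", "AY123456.1"),
            ("gi|notdigits|x", "gi|notdigits|x"),
        ],
    )
    def test_dialects(self, subject, expected):
        assert extract_record_id(subject) == expected

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            extract_record_id("")


class TestRunSearch:
    def test_chunked_equals_unchunked_after_filtering(self, toy, tmp_path):
        """Input chopping must not change the filtered hit table."""
        ds, _ = toy
        seqs, _ = parse_and_rename(ds.fasta)
        runner = fixtures.stub_runner(ds.hits)
        lengths = {s.new_id: len(s.sequence) for s in seqs}
        tables = {}
        for threads in (1, 2, 4):
            out = tmp_path / f"res_{threads}.tsv"
            run_search(seqs, "toydb", out, threads=threads, runner=runner)
            tables[threads] = filter_hits(parse_tabular(out, lengths))
        assert tables[1] == tables[2] == tables[4]

    def test_single_thread_concatenation_is_whole_file(self, toy, tmp_path):
        ds, _ = toy
        seqs, _ = parse_and_rename(ds.fasta)
        out = tmp_path / "res.tsv"
        run_search(seqs, "toydb", out, threads=1, runner=fixtures.stub_runner(ds.hits))
        assert sorted(out.read_text().splitlines()) == sorted(
            line for line in ds.hits.read_text().splitlines() if line
        )

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            run_search([], "db", "out.tsv")
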