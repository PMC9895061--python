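"""Parsing and round-trip behavior of the input readers."""

import io
import random

import pytest

from litnet import (
    AbstractCorpus,
    AbstractRecord,
    EmptyInputError,
    GeneList,
    ParseError,
    fetch_remote_abstracts,
    read_corpus,
    read_gene_list,
    read_gene_pmid_map,
    write_corpus,
)
from litnet.corpus_io import LitnetError

from conftest import stream


class TestGeneList:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("PRDX1\nTXN\nPRDX1\n", ("PRDX1", "TXN")),          # dedupe keeps first
            ("prdx1\nPRDX1\n", ("prdx1",)),                      # case-fold dedupe
            ("# header\nKEAP1\t2.3\n", ("KEAP1",)),              # comments + columns
            ("\nA\n\n  \nB\n", ("A", "B")),                      # blank lines skipped
            ("A 1.5 x\nB\n", ("A", "B")),                        # space-separated columns
        ],
    )
    def test_parsing(self, text, expected):
        assert read_gene_list(stream(text)).symbols == expected

    def test_annotations_carried_through(self):
        gl = read_gene_list(stream("KEAP1\t2.3\tup\nTXN\n"))
        assert gl.annotations["KEAP1"] == ("2.3", "up")
        assert "TXN" not in gl.annotations

    def test_duplicate_warning_logged(self, caplog):
        with caplog.at_level("WARNING", logger="litnet"):
            read_gene_list(stream("prdx1\nPRDX1\n"))
        assert sum("duplicate" in r.message for r in caplog.records) == 1

    def test_empty_list_is_an_error(self):
        with pytest.raises(EmptyInputError, match="empty gene list"):
            read_gene_list(stream("# only a comment\n"))

    def test_empty_first_column_names_the_line(self):
        with pytest.raises(ParseError, match="line 2"):
            read_gene_list(stream("A\n\t2.3\n"))

    def test_constructor_rejects_casefold_duplicates(self):
        with pytest.raises(ValueError):
            GeneList(("a", "A"))


class TestCorpus:
    def test_jsonl_single_record(self):
        corpus = read_corpus(stream('{"pmid": "1", "title": "t", "abstract": "a"}\n'))
        assert len(corpus) == 1
        assert corpus["1"] == AbstractRecord("1", "t", "a")

    def test_jsonl_duplicate_pmid_last_wins(self, caplog):
        text = '{"pmid": "7", "abstract": "first"}\n{"pmid": "7", "abstract": "second"}\n'
        with caplog.at_level("WARNING", logger="litnet"):
            corpus = read_corpus(stream(text))
        assert len(corpus) == 1
        assert corpus["7"].body == "second"
        assert any("duplicate abstract id" in r.message for r in caplog.records)

    def test_jsonl_malformed_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            read_corpus(stream('{"pmid": "1"}\n{not json}\n'))

    def test_medline_continuation_lines_space_joined(self):
        text = (
            "PMID- 101\n"
            "TI  - A title\n"
            "AB  - First fragment of the abstract\n"
            "      second fragment continued.\n"
            "\n"
        )
        corpus = read_corpus(stream(text), format="medline")
        assert corpus["101"].body == "First fragment of the abstract second fragment continued."

    def test_medline_record_without_pmid_skipped(self, caplog):
        text = "TI  - Orphan record\n\nPMID- 5\nTI  - Kept\n\n"
        with caplog.at_level("WARNING", logger="litnet"):
            corpus = read_corpus(stream(text), format="medline")
        assert list(corpus.ids()) == ["5"]

    def test_jsonl_round_trip(self, tiny_corpus):
        buf = io.StringIO()
        write_corpus(tiny_corpus, buf)
        again = read_corpus(stream(buf.getvalue()))
        assert again == tiny_corpus
        buf2 = io.StringIO()
        write_corpus(again, buf2)
        assert buf2.getvalue() == buf.getvalue()


class TestGenePmidMap:
    def test_set_semantics_and_casefold(self, tiny_gene_list):
        rows = "9606\tPRDX1\t10\n9606\tPRDX1\t10\n9606\tprdx1\t11\n9606\tTXN\t12\n"
        m = read_gene_pmid_map(stream(rows), tiny_gene_list)
        assert m.pmids("PRDX1") == {"10", "11"}
        assert m.pmids("TXN") == {"12"}

    def test_unmapped_distinct_from_empty(self, tiny_gene_list):
        m = read_gene_pmid_map(stream("9606\tPRDX1\t10\n"), tiny_gene_list)
        assert m.is_unmapped("KEAP1")
        assert m.pmids("KEAP1") == frozenset()
        assert not m.is_unmapped("PRDX1")

    def test_two_column_dialect_and_header(self, tiny_gene_list):
        m = read_gene_pmid_map(stream("gene\tpmid\nTXN\t44\n"), tiny_gene_list)
        assert m.pmids("TXN") == {"44"}

    def test_restriction_to_gene_list(self, tiny_gene_list):
        m = read_gene_pmid_map(stream("9606\tESR1\t99\n9606\tTXN\t44\n"), tiny_gene_list)
        assert set(m.mapping) <= set(tiny_gene_list.symbols)

    def test_short_row_is_an_error(self, tiny_gene_list):
        with pytest.raises(ParseError, match="line 2"):
            read_gene_pmid_map(stream("PRDX1\t1\nPRDX1\n"), tiny_gene_list)

    def test_row_order_does_not_matter(self, tiny_gene_list):
        rows = [f"9606\tPRDX1\t{i}" for i in range(20)] + ["9606\tTXN\t50"]
        m1 = read_gene_pmid_map(stream("\n".join(rows) + "\n"), tiny_gene_list)
        random.Random(0).shuffle(rows)
        m2 = read_gene_pmid_map(stream("\n".join(rows) + "\n"), tiny_gene_list)
        assert m1.mapping == m2.mapping
        assert m1.unmapped == m2.unmapped


class FakeClient:
    """Offline stand-in for the E-utilities client, recording each call."""

    def __init__(self, hits):
        self.hits = hits
        self.calls = 0

    def gene_pmids(self, symbol):
        self.calls += 1
        return sorted(self.hits.get(symbol, {}))

    def fetch_abstracts(self, pmids):
        self.calls += 1
        return [AbstractRecord(p, title=f"title {p}", body=f"body {p}") for p in pmids]


class TestRemoteFetchContract:
    HITS = {"PRDX1": {"10", "11"}, "TXN": {"12"}}

    def test_cold_then_warm_cache(self, tiny_gene_list, tmp_path):
        client = FakeClient(self.HITS)
        corpus1, map1 = fetch_remote_abstracts(tiny_gene_list, tmp_path, client=client)
        assert client.calls > 0
        assert map1.pmids("PRDX1") == {"10", "11"}
        # KEAP1 was looked up and has zero hits: empty set, not unmapped
        assert map1.pmids("KEAP1") == frozenset() and not map1.is_unmapped("KEAP1")

        calls_before = client.calls
        corpus2, map2 = fetch_remote_abstracts(tiny_gene_list, tmp_path, client=client)
        assert client.calls == calls_before  # zero network requests on warm cache
        assert corpus2 == corpus1
        assert map2.mapping == map1.mapping

    def test_rate_limit_spacing(self, tiny_gene_list, tmp_path):
        now = [0.0]
        sleeps = []

        def clock():
            return now[0]

        def sleep(dt):
            sleeps.append(dt)
            now[0] += dt

        fetch_remote_abstracts(
            tiny_gene_list, tmp_path, rate_limit=3.0,
            client=FakeClient(self.HITS), sleep=sleep, clock=clock,
        )
        # 3 genes x 2 calls = 6 requests; every inter-request gap >= 1/3 s
        assert len(sleeps) >= 5
        assert all(dt >= (1 / 3) - 1e-9 for dt in sleeps)

    def test_failure_names_gene_and_preserves_partial_cache(self, tiny_gene_list, tmp_path):
        class Failing(FakeClient):
            def gene_pmids(self, symbol):
                if symbol == "TXN":
                    raise OSError("connection reset")
                return super().gene_pmids(symbol)

        with pytest.raises(LitnetError, match="TXN"):
            fetch_remote_abstracts(tiny_gene_list, tmp_path, client=Failing(self.HITS))
        assert (tmp_path / "corpus.jsonl").exists()
        partial = read_corpus(tmp_path / "corpus.jsonl")
        assert set(partial.ids()) == {"10", "11"}  # PRDX1 succeeded before the failure
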