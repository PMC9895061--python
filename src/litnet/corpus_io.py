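"""Input parsing for gene lists, abstract corpora and gene→PMID mappings.

The ranking pipeline consumes four plain-text inputs:

* a gene list (one symbol per line, or TSV whose first column is the symbol),
* an abstract corpus (JSONL with ``pmid``/``title``/``abstract`` fields, or a
  PubMed MEDLINE flat file),
* a gene2pubmed-style TSV linking gene symbols to abstract identifiers,
* (elsewhere) a STRING-format protein interaction edge list.

Gene identity throughout the package is case-fold symbol match: ``prdx1`` and
``PRDX1`` are the same gene, and the spelling that appears first in the user's
list is the canonical one.  An optional alias table can be layered on top by
pre-mapping symbols before they reach these readers.

A gene can be *unmapped* (no row in the mapping file — we know nothing about
its literature) or mapped to an *empty set* (we looked and found no abstracts).
The two are kept distinct so reports can say "no literature link" rather than
"keyword never matched".
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence, TextIO

logger = logging.getLogger("litnet")


class LitnetError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(LitnetError):
    """A malformed line in one of the text inputs.

    Carries the 1-based line number so command-line users can find the row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(LitnetError):
    """An input that parsed cleanly but contains nothing usable."""


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneList:
    """An ordered, deduplicated list of query gene symbols.

    ``annotations`` carries any extra TSV columns (e.g. log2 fold change)
    verbatim; they never influence scoring.
    """

    symbols: tuple[str, ...]
    annotations: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.symbols:
            if not s:
                raise ValueError("gene symbols must be non-empty")
            key = s.casefold()
            if key in seen:
                raise ValueError(f"duplicate gene symbol (case-fold): {s!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self.casefold_index()

    def casefold_index(self) -> dict[str, str]:
        """Map each case-folded symbol to its canonical (as-input) spelling."""
        return {s.casefold(): s for s in self.symbols}


def read_gene_list(source: TextIO | str | Path) -> GeneList:
    """Parse a gene list from line-oriented text.

    The first whitespace-delimited (tab-preferred) column of each line is the
    symbol; remaining columns are kept as annotations.  Lines starting with
    ``#`` and blank lines are skipped.  Duplicate symbols (case-fold) keep the
    first occurrence; each drop is logged as a warning.
    """
    stream = _as_stream(source)
    symbols: list[str] = []
    annotations: dict[str, tuple[str, ...]] = {}
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        symbol = cols[0].strip()
        if not symbol:
            raise ParseError("first column (gene symbol) is empty", lineno)
        key = symbol.casefold()
        if key in seen:
            logger.warning("dropping duplicate gene symbol %r (line %d)", symbol, lineno)
            continue
        seen.add(key)
        symbols.append(symbol)
        extra = tuple(c.strip() for c in cols[1:])
        if extra:
            annotations[symbol] = extra
    if not symbols:
        raise EmptyInputError("empty gene list")
    return GeneList(tuple(symbols), annotations)


# ---------------------------------------------------------------------------
# Abstract corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbstractRecord:
    """One abstract: an identifier (PMID role), a title and a body."""

    abstract_id: str
    title: str = ""
    body: str = ""


class AbstractCorpus:
    """A collection of :class:`AbstractRecord` keyed by abstract id."""

    def __init__(self, records: Iterable[AbstractRecord] = ()):
        self._records: dict[str, AbstractRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: AbstractRecord, warn_on_duplicate: bool = False) -> None:
        if warn_on_duplicate and record.abstract_id in self._records:
            logger.warning("duplicate abstract id %s: keeping the later record", record.abstract_id)
        self._records[record.abstract_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, abstract_id: str) -> bool:
        return abstract_id in self._records

    def __getitem__(self, abstract_id: str) -> AbstractRecord:
        return self._records[abstract_id]

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self._records.values())

    def ids(self) -> Iterable[str]:
        return self._records.keys()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbstractCorpus):
            return NotImplemented
        return self._records == other._records


def read_corpus(source: TextIO | str | Path, format: str = "jsonl") -> AbstractCorpus:
    """Read an abstract corpus from JSONL or MEDLINE flat-file text.

    JSONL: one object per line with fields ``pmid``, ``title``, ``abstract``
    (missing title/abstract default to the empty string).  MEDLINE: records
    separated by blank lines with ``PMID``/``TI``/``AB`` tags; continuation
    lines are joined with single spaces; records without a PMID are skipped
    with a warning.  Duplicate ids: the last record wins, with a warning.
    """
    stream = _as_stream(source)
    if format == "jsonl":
        return _read_jsonl(stream)
    if format == "medline":
        return _read_medline(stream)
    raise ValueError(f"unknown corpus format: {format!r} (expected 'jsonl' or 'medline')")


def _read_jsonl(stream: TextIO) -> AbstractCorpus:
    corpus = AbstractCorpus()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON: {exc.msg}", lineno) from exc
        if not isinstance(obj, dict) or "pmid" not in obj:
            raise ParseError("JSONL record must be an object with a 'pmid' field", lineno)
        rec = AbstractRecord(
            abstract_id=str(obj["pmid"]),
            title=str(obj.get("title", "") or ""),
            body=str(obj.get("abstract", "") or ""),
        )
        corpus.add(rec, warn_on_duplicate=True)
    return corpus


def _read_medline(stream: TextIO) -> AbstractCorpus:
    # Bio.Medline implements the tag + continuation-line grammar of PubMed's
    # flat-file export; we only consume PMID/TI/AB.
    from Bio import Medline

    corpus = AbstractCorpus()
    for rec in Medline.parse(stream):
        pmid = rec.get("PMID")
        if not pmid:
            logger.warning("skipping MEDLINE record without PMID (TI=%r)", rec.get("TI", "")[:40])
            continue
        corpus.add(
            AbstractRecord(abstract_id=str(pmid), title=rec.get("TI", ""), body=rec.get("AB", "")),
            warn_on_duplicate=True,
        )
    return corpus


def write_corpus(corpus: AbstractCorpus, destination: TextIO | str | Path) -> None:
    """Serialize a corpus to JSONL (the package's canonical on-disk form)."""
    close, stream = _as_output_stream(destination)
    try:
        for rec in corpus:
            stream.write(
                json.dumps(
                    {"pmid": rec.abstract_id, "title": rec.title, "abstract": rec.body},
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Gene → abstract-id mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePmidMap:
    """Per-gene abstract-id sets, restricted to a query gene list.

    ``mapping`` holds canonical symbols → frozen sets of abstract ids.
    ``unmapped`` holds query genes that had no row at all in the source file;
    these are distinct from genes mapped to the empty set.
    """

    mapping: Mapping[str, frozenset[str]]
    unmapped: frozenset[str] = frozenset()

    def pmids(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def is_unmapped(self, gene: str) -> bool:
        return gene in self.unmapped


def read_gene_pmid_map(source: TextIO | str | Path, gene_list: GeneList) -> GenePmidMap:
    """Parse a gene2pubmed-style TSV restricted to ``gene_list``.

    Accepts three columns (tax_id, symbol, pmid) or two (symbol, pmid),
    whitespace- or tab-separated, with an optional header line.  Symbols match
    the gene list case-fold; rows for other genes are ignored.  PMIDs are
    deduplicated per gene.
    """
    stream = _as_stream(source)
    index = gene_list.casefold_index()
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        cols = [c.strip() for c in cols if c.strip()]
        if len(cols) < 2:
            raise ParseError(f"expected at least 2 columns, found {len(cols)}", lineno)
        if len(cols) >= 3:
            symbol, pmid = cols[1], cols[2]
        else:
            symbol, pmid = cols[0], cols[1]
        if lineno == 1 and _looks_like_header(symbol, pmid):
            continue
        canonical = index.get(symbol.casefold())
        if canonical is None:
            continue
        sets.setdefault(canonical, set()).add(pmid)
    unmapped = frozenset(s for s in gene_list.symbols if s not in sets)
    mapping = {g: frozenset(v) for g, v in sets.items()}
    return GenePmidMap(mapping=mapping, unmapped=unmapped)


def _looks_like_header(symbol: str, pmid: str) -> bool:
    return not pmid.isdigit() and symbol.casefold() in {"gene", "symbol", "gene_symbol", "geneid", "gene_id"}


def write_gene_pmid_map(pmid_map: GenePmidMap, destination: TextIO | str | Path) -> None:
    """Serialize a mapping as a two-column symbol→pmid TSV (sorted, stable)."""
    close, stream = _as_output_stream(destination)
    try:
        for gene in sorted(pmid_map.mapping):
            for pmid in sorted(pmid_map.mapping[gene]):
                stream.write(f"{gene}\t{pmid}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Optional cached remote fetch (NCBI E-utilities)
# ---------------------------------------------------------------------------

class EntrezAbstractClient:
    """Thin E-utilities client: symbol → PMID list, PMIDs → abstracts.

    Queries PubMed with ``<symbol>[sym]`` (gene-field symbol search); this is
    one of several possible gene→publication linkages and is documented as a
    choice, not as fidelity to any particular web service.
    """

    def __init__(self, email: str, retmax: int = 1000):
        from Bio import Entrez

        Entrez.email = email
        self._entrez = Entrez
        self.retmax = retmax

    def gene_pmids(self, symbol: str) -> list[str]:
        handle = self._entrez.esearch(db="pubmed", term=f"{symbol}[sym]", retmax=self.retmax)
        result = self._entrez.read(handle)
        handle.close()
        return [str(i) for i in result.get("IdList", [])]

    def fetch_abstracts(self, pmids: Sequence[str]) -> list[AbstractRecord]:
        if not pmids:
            return []
        from Bio import Medline

        handle = self._entrez.efetch(db="pubmed", id=",".join(pmids), rettype="medline", retmode="text")
        records = [
            AbstractRecord(abstract_id=str(r["PMID"]), title=r.get("TI", ""), body=r.get("AB", ""))
            for r in Medline.parse(handle)
            if r.get("PMID")
        ]
        handle.close()
        return records


CACHE_CORPUS = "corpus.jsonl"
CACHE_MAP = "gene_pmid_map.tsv"


def fetch_remote_abstracts(
    genes: GeneList,
    cache_dir: str | Path,
    rate_limit: float = 3.0,
    client=None,
    email: str = "",
    sleep: Callable[[float], None] = time.sleep,
    clock: Callable[[], float] = time.monotonic,
) -> tuple[AbstractCorpus, GenePmidMap]:
    """Fetch per-gene PMIDs and abstracts, caching everything to ``cache_dir``.

    A warm cache (``corpus.jsonl`` + ``gene_pmid_map.tsv`` present) is read
    back verbatim with zero network requests.  Requests are spaced at least
    ``1 / rate_limit`` seconds apart.  On network failure the partial cache is
    preserved and the error names the gene being fetched.

    ``client``, ``sleep`` and ``clock`` are injectable for offline testing;
    the default client speaks the E-utilities protocol via Bio.Entrez.
    A gene PubMed knows nothing about is mapped to the empty set (it was
    looked up), never flagged unmapped.
    """
    cache = Path(cache_dir)
    corpus_path = cache / CACHE_CORPUS
    map_path = cache / CACHE_MAP
    if corpus_path.exists() and map_path.exists():
        corpus = read_corpus(corpus_path, format="jsonl")
        pmid_map = read_gene_pmid_map(map_path, genes)
        # every listed gene was fetched when the cache was written
        pmid_map = GenePmidMap(
            mapping={g: pmid_map.pmids(g) for g in genes.symbols},
            unmapped=frozenset(),
        )
        return corpus, pmid_map

    if client is None:
        if not email:
            raise LitnetError("remote fetch requires an email address (NCBI E-utilities policy)")
        client = EntrezAbstractClient(email=email)

    cache.mkdir(parents=True, exist_ok=True)
    min_interval = 1.0 / rate_limit if rate_limit > 0 else 0.0
    last_request = [-float("inf")]

    def throttled(call, *args):
        wait = last_request[0] + min_interval - clock()
        if wait > 0:
            sleep(wait)
        last_request[0] = clock()
        return call(*args)

    corpus = AbstractCorpus()
    mapping: dict[str, frozenset[str]] = {}
    for gene in genes.symbols:
        try:
            pmids = throttled(client.gene_pmids, gene)
            records = throttled(client.fetch_abstracts, pmids)
        except Exception as exc:  # preserve partial cache before re-raising
            _persist_cache(corpus, mapping, corpus_path, map_path)
            raise LitnetError(f"network fetch failed for gene {gene!r}: {exc}") from exc
        mapping[gene] = frozenset(pmids)
        for rec in records:
            corpus.add(rec)
        logger.info("fetched %d abstracts for %s", len(records), gene)
    _persist_cache(corpus, mapping, corpus_path, map_path)
    return corpus, GenePmidMap(mapping=mapping, unmapped=frozenset())


def _persist_cache(
    corpus: AbstractCorpus,
    mapping: Mapping[str, frozenset[str]],
    corpus_path: Path,
    map_path: Path,
) -> None:
    write_corpus(corpus, corpus_path)
    write_gene_pmid_map(GenePmidMap(mapping=dict(mapping)), map_path)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_stream(source: TextIO | str | Path) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _as_output_stream(destination: TextIO | str | Path) -> tuple[bool, TextIO]:
    if isinstance(destination, (str, Path)):
        return True, open(destination, "w", encoding="utf-8")
    return False, destination
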