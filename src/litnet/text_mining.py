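"""Keyword text mining: per-gene match counts, hit ratios and Text Scores.

For each query gene the user's keyword (a word or phrase, e.g. "reactive
oxygen species") is scanned across all of that gene's linked abstracts.
Counting is abstract-level: an abstract either contains the phrase or it does
not, however many times it repeats.  The per-gene statistics are

    record_number  = number of linked abstracts present in the corpus
    match_number   = number of those abstracts containing the keyword
    hit_ratio      = match_number / record_number   (0 when record_number = 0)

and hit ratios are max-normalized across the list into Text Scores in [0, 1],
so the best-supported gene scores exactly 1 and the text component is
commensurate with the PPI component before the two are summed.

Matching is exact-phrase over normalized text: case-folded, punctuation and
hyphens mapped to spaces ("reactive-oxygen species" matches), no stemming and
no synonym expansion ("ROS" does not match "reactive oxygen species").
Titles are searched along with abstract bodies by default, mirroring how
PubMed keyword queries behave; ``search_fields="abstract"`` restricts to
bodies only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import AbstractCorpus, AbstractRecord, GeneList, GenePmidMap, LitnetError

_NON_WORD = re.compile(r"[\W_]+", re.UNICODE)

SEARCH_FIELDS = ("title+abstract", "abstract")


@dataclass(frozen=True)
class Keyword:
    """A user keyword; normalized to a non-empty token phrase."""

    phrase: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"keyword {self.phrase!r} contains no searchable tokens")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(normalize_text(self.phrase))


@dataclass(frozen=True)
class TextMiningResult:
    """Per-gene literature statistics (see module docstring for definitions)."""

    gene: str
    record_number: int
    match_number: int
    hit_ratio: float
    zero_records: bool = False
    unmapped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.match_number <= self.record_number:
            raise ValueError(
                f"{self.gene}: match_number {self.match_number} outside "
                f"[0, record_number={self.record_number}]"
            )


def normalize_text(text: str) -> list[str]:
    """Case-fold, map punctuation/hyphens to spaces, split into tokens."""
    return [t for t in _NON_WORD.split(text.casefold()) if t]


def match_keyword(
    record: AbstractRecord,
    keyword: Keyword,
    search_fields: str = "title+abstract",
) -> bool:
    """True iff the keyword phrase occurs contiguously in the abstract.

    The phrase must appear as a contiguous run of tokens in the normalized
    title+body text (or body only, per ``search_fields``).  Multiple
    occurrences still count once: matching is abstract-level.
    """
    if search_fields not in SEARCH_FIELDS:
        raise ValueError(f"search_fields must be one of {SEARCH_FIELDS}, got {search_fields!r}")
    text = record.body if search_fields == "abstract" else f"{record.title} {record.body}"
    tokens = normalize_text(text)
    phrase = keyword.tokens
    k = len(phrase)
    if k == 0 or k > len(tokens):
        return False
    first = phrase[0]
    return any(
        tokens[i] == first and tuple(tokens[i : i + k]) == phrase
        for i in range(len(tokens) - k + 1)
    )


def count_matches(
    gene: str,
    keyword: Keyword,
    corpus: AbstractCorpus,
    pmid_map: GenePmidMap,
    search_fields: str = "title+abstract",
) -> TextMiningResult:
    """Scan one gene's abstracts and compute its hit ratio.

    Only mapped abstract ids actually present in the corpus count toward
    record_number; ids pointing outside the corpus are ignored (the mapping
    file may reference abstracts that were never downloaded).  A gene with no
    usable abstracts gets hit_ratio 0 and the zero-record flag.
    """
    unmapped = pmid_map.is_unmapped(gene)
    ids = sorted(i for i in pmid_map.pmids(gene) if i in corpus)
    record_number = len(ids)
    match_number = sum(1 for i in ids if match_keyword(corpus[i], keyword, search_fields))
    if record_number == 0:
        return TextMiningResult(gene, 0, 0, 0.0, zero_records=True, unmapped=unmapped)
    return TextMiningResult(
        gene, record_number, match_number, match_number / record_number, unmapped=unmapped
    )


def mine_gene_list(
    gene_list: GeneList,
    keyword: Keyword,
    corpus: AbstractCorpus,
    pmid_map: GenePmidMap,
    search_fields: str = "title+abstract",
) -> list[TextMiningResult]:
    """Run :func:`count_matches` for every gene in the query list."""
    return [count_matches(g, keyword, corpus, pmid_map, search_fields) for g in gene_list.symbols]


def text_scores(results: Iterable[TextMiningResult]) -> dict[str, float]:
    """Max-normalize hit ratios into Text Scores.

    text_score(g) = hit_ratio(g) / max hit_ratio over the list when the max is
    positive; all zeros otherwise.  Zeros are preserved and the best gene
    scores exactly 1.
    """
    results = list(results)
    if not results:
        raise LitnetError("no genes to score")
    top = max(r.hit_ratio for r in results)
    if top <= 0:
        return {r.gene: 0.0 for r in results}
    return {r.gene: r.hit_ratio / top for r in results}


def mining_table(
    results: Sequence[TextMiningResult], scores: Mapping[str, float]
) -> pd.DataFrame:
    """Tabulate per-gene text-mining output (TSV-exportable)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "record_number": [r.record_number for r in results],
            "match_number": [r.match_number for r in results],
            "hit_ratio": [r.hit_ratio for r in results],
            "text_score": [scores[r.gene] for r in results],
            "zero_record_flag": [r.zero_records for r in results],
        }
    )
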