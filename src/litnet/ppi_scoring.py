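"""Protein–protein-interaction scoring over the query gene list.

Edges come from a STRING-style links file (``protein1 protein2
combined_score``, confidence an integer on the 0–1000 scale).  The network is
undirected: STRING files list both directions of each pair, so (a,b)/(b,a)
rows collapse to one edge keeping the maximum confidence, and self-loops are
dropped.  Edges below ``min_confidence`` (default 400, STRING's conventional
medium-confidence cutoff) are discarded at load time.

The PPI Score of a gene is its degree in the subgraph induced on the query
list — genes interacting with more listed genes score higher — max-normalized
to [0, 1] so it is commensurate with the Text Score.  Confidences do not
weight the degree by default (interactions are counted, not summed); set
``weight_by_confidence=True`` to use sum(confidence)/1000 instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, TextIO

import networkx as nx
import pandas as pd

from .corpus_io import GeneList, LitnetError, ParseError, _as_stream, logger

DEFAULT_MIN_CONFIDENCE = 400

_HEADER_TOKENS = {"protein1", "protein2", "combined_score", "node1", "node2", "score"}


def read_ppi_edges(
    source: TextIO | str,
    min_confidence: int = DEFAULT_MIN_CONFIDENCE,
    name_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Load a STRING-format edge list into an undirected confidence graph.

    ``name_map`` optionally translates identifiers (e.g. STRING protein ids)
    to gene symbols; rows with an identifier missing from the map are skipped
    with a warning.  Node names keep their input spelling; matching against
    the query list is case-fold and happens in :func:`induced_subgraph`.
    """
    stream = _as_stream(source)
    graph = nx.Graph()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise ParseError(f"expected 3 columns (protein1 protein2 combined_score), found {len(cols)}", lineno)
        a, b, score_text = cols[0], cols[1], cols[2]
        if lineno == 1 and (a.casefold() in _HEADER_TOKENS or not _is_int(score_text)):
            continue
        if not _is_int(score_text):
            raise ParseError(f"non-integer combined_score {score_text!r}", lineno)
        confidence = int(score_text)
        if name_map is not None:
            if a not in name_map or b not in name_map:
                missing = a if a not in name_map else b
                logger.warning("line %d: identifier %r not in name map, row skipped", lineno, missing)
                continue
            a, b = name_map[a], name_map[b]
        if a.casefold() == b.casefold():  # self-loop
            continue
        if confidence < min_confidence:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], confidence)
        else:
            graph.add_edge(a, b, confidence=confidence)
    return graph


def _is_int(text: str) -> bool:
    try:
        int(text)
    except ValueError:
        return False
    return True


def induced_subgraph(network: nx.Graph, genes: GeneList) -> nx.Graph:
    """Subgraph on the query genes: every listed gene is a node (isolated if
    unconnected); edges require both endpoints in the list (case-fold match).

    Nodes are relabelled to the canonical spellings from the gene list.
    """
    if len(genes) == 0:
        raise LitnetError("no genes")
    index = genes.casefold_index()
    sub = nx.Graph()
    sub.add_nodes_from(genes.symbols)
    for a, b, data in network.edges(data=True):
        ca, cb = index.get(a.casefold()), index.get(b.casefold())
        if ca is None or cb is None:
            continue
        if sub.has_edge(ca, cb):
            sub[ca][cb]["confidence"] = max(sub[ca][cb]["confidence"], data["confidence"])
        else:
            sub.add_edge(ca, cb, confidence=data["confidence"])
    return sub


@dataclass(frozen=True)
class PPIScoreTable:
    """Per-gene in-list degree and its max-normalized score."""

    degree: Mapping[str, int]
    score: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.degree)
        return pd.DataFrame(
            {
                "gene": genes,
                "ppi_degree": [self.degree[g] for g in genes],
                "ppi_score": [self.score[g] for g in genes],
            }
        )


def ppi_scores(subgraph: nx.Graph, weight_by_confidence: bool = False) -> PPIScoreTable:
    """Score every query gene by its connectivity within the list.

    Default: score = degree / max degree (all zeros when the subgraph has no
    edges).  Weighted mode replaces the degree with sum(confidence)/1000 over
    incident edges before the same max-normalization.
    """
    degree = {g: int(d) for g, d in subgraph.degree()}
    if weight_by_confidence:
        raw = {
            g: sum(data["confidence"] for _, _, data in subgraph.edges(g, data=True)) / 1000.0
            for g in subgraph.nodes()
        }
    else:
        raw = {g: float(d) for g, d in degree.items()}
    top = max(raw.values(), default=0.0)
    if top <= 0:
        return PPIScoreTable(degree, {g: 0.0 for g in raw})
    return PPIScoreTable(degree, {g: v / top for g, v in raw.items()})
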