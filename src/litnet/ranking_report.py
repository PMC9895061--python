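"""Final scoring, ranking, and report/graph export.

The final (total) score of a gene is the plain sum of its Text Score and its
PPI Score, so it lives in [0, 2].  Genes are ranked by descending final
score; ties break by higher text score, then case-fold lexicographic symbol,
giving every gene a unique 1-based rank.  The full ranking is always
computed — ``top_n`` is a presentation filter, so a gene's rank is stable
under truncation.

Exports:

* a TSV table (scores at 6 decimal places) with a provenance footer of
  comment lines recording the parameters and input digests of the run;
* the induced interaction subgraph restricted to the reported genes, as
  node-link JSON, GraphML, or a self-contained interactive HTML page.  Node
  shade values map final scores linearly onto a light-to-dark blue ramp:
  higher score, darker node.

All exports are deterministic: the same inputs and parameters yield
byte-identical documents.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import networkx as nx
import pandas as pd
from networkx.readwrite import json_graph

from . import __version__
from .corpus_io import LitnetError, _as_output_stream
from .text_mining import TextMiningResult

GRAPH_FORMATS = ("node_link_json", "graphml", "html")

# light-to-dark blue ramp endpoints (RGB)
_RAMP_LIGHT = (222, 235, 247)
_RAMP_DARK = (8, 48, 107)


@dataclass(frozen=True)
class ReportRow:
    rank: int
    gene: str
    text_score: float
    ppi_score: float
    final_score: float
    record_number: int
    match_number: int
    ppi_degree: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnrichmentReport:
    """Ranked per-gene scores plus the score-shaded graph payload."""

    rows: tuple[ReportRow, ...]
    graph: nx.Graph
    parameters: Mapping[str, object] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return [r.gene for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows]).assign(
            flags=[";".join(r.flags) or "-" for r in self.rows]
        )


def combine_scores(
    text: Mapping[str, float], ppi: Mapping[str, float]
) -> dict[str, float]:
    """final_score(g) = text_score(g) + ppi_score(g).

    Both tables must cover exactly the same gene set; a mismatch reports the
    symmetric difference.
    """
    if set(text) != set(ppi):
        diff = sorted(set(text) ^ set(ppi))
        raise LitnetError(f"text/PPI gene sets differ: {diff}")
    return {g: text[g] + ppi[g] for g in text}


def rank_genes(
    final: Mapping[str, float], text: Mapping[str, float]
) -> list[tuple[int, str]]:
    """Order genes by final score and assign unique 1-based ranks.

    Sort key: final score descending, text score descending, case-fold
    lexicographic symbol ascending.  Ties never share a rank.
    """
    if not final:
        raise LitnetError("no genes to rank")
    ordered = sorted(
        final, key=lambda g: (-final[g], -text.get(g, 0.0), g.casefold(), g)
    )
    return [(i, g) for i, g in enumerate(ordered, start=1)]


def build_report(
    mining_results: Sequence[TextMiningResult],
    text: Mapping[str, float],
    ppi_table,
    subgraph: nx.Graph,
    parameters: Mapping[str, object] | None = None,
) -> EnrichmentReport:
    """Assemble the full ranked report from the per-stage outputs."""
    by_gene = {r.gene: r for r in mining_results}
    final = combine_scores(text, dict(ppi_table.score))
    rows = []
    for rank, gene in rank_genes(final, text):
        tm = by_gene[gene]
        flags = []
        if tm.unmapped:
            flags.append("unmapped")
        elif tm.zero_records:
            flags.append("zero_records")
        if ppi_table.degree.get(gene, 0) == 0:
            flags.append("isolated")
        rows.append(
            ReportRow(
                rank=rank,
                gene=gene,
                text_score=text[gene],
                ppi_score=ppi_table.score[gene],
                final_score=final[gene],
                record_number=tm.record_number,
                match_number=tm.match_number,
                ppi_degree=ppi_table.degree.get(gene, 0),
                flags=tuple(flags),
            )
        )
    graph = _shaded_graph(subgraph, {r.gene: r.final_score for r in rows})
    return EnrichmentReport(tuple(rows), graph, dict(parameters or {}))


def _shaded_graph(subgraph: nx.Graph, final: Mapping[str, float]) -> nx.Graph:
    graph = nx.Graph()
    top = max(final.values(), default=0.0)
    for gene in sorted(final, key=str.casefold):
        score = final[gene]
        graph.add_node(
            gene,
            final_score=float(score),
            shade=float(score / top) if top > 0 else 0.0,
        )
    for a, b, data in subgraph.edges(data=True):
        if a in final and b in final:
            graph.add_edge(a, b, confidence=int(data["confidence"]))
    return graph


def top_n(report: EnrichmentReport, n: int = 50) -> EnrichmentReport:
    """Keep the first min(n, total) rows and restrict the graph payload.

    Presentation-only: relative order is untouched and full-list ranks are
    preserved in the retained rows.
    """
    if n < 1:
        raise ValueError(f"top_n requires n >= 1, got {n}")
    rows = report.rows[:n]
    kept = {r.gene: r.final_score for r in rows}
    graph = _shaded_graph(report.graph.subgraph(kept).copy(), kept)
    # shade is defined against the full ranking's maximum, not the slice's
    full_top = max((r.final_score for r in report.rows), default=0.0)
    for gene in graph.nodes:
        graph.nodes[gene]["shade"] = kept[gene] / full_top if full_top > 0 else 0.0
    return replace(report, rows=rows, graph=graph)


def rank_of(report: EnrichmentReport, gene: str) -> int | None:
    """1-based rank of ``gene`` in the report, or None if it was not scored."""
    key = gene.casefold()
    for row in report.rows:
        if row.gene.casefold() == key:
            return row.rank
    return None


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "rank",
    "gene",
    "final_score",
    "text_score",
    "ppi_score",
    "record_number",
    "match_number",
    "ppi_degree",
    "flags",
)


def export_table(report: EnrichmentReport, destination: TextIO | str | Path) -> None:
    """Write the ranked score table as TSV with a provenance footer.

    Scores print with 6 decimal places.  The footer is a block of ``#``
    comment lines echoing the run parameters (keyword, thresholds,
    normalization choices, tool version, input digests) so the file is
    self-describing and byte-reproducible.
    """
    if not report.rows:
        raise LitnetError("nothing to export")
    close, stream = _as_output_stream(destination)
    try:
        stream.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in report.rows:
            stream.write(
                f"{r.rank}\t{r.gene}\t{r.final_score:.6f}\t{r.text_score:.6f}\t"
                f"{r.ppi_score:.6f}\t{r.record_number}\t{r.match_number}\t"
                f"{r.ppi_degree}\t{';'.join(r.flags) or '-'}\n"
            )
        stream.write(f"# litnet {__version__}\n")
        for key in sorted(report.parameters):
            stream.write(f"# {key} = {report.parameters[key]}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def shade_to_color(shade: float) -> str:
    """Map a shade value in [0, 1] onto the light-to-dark blue ramp (hex)."""
    shade = min(max(shade, 0.0), 1.0)
    rgb = (
        round(light + shade * (dark - light))
        for light, dark in zip(_RAMP_LIGHT, _RAMP_DARK)
    )
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def export_graph(
    report: EnrichmentReport, format: str, destination: TextIO | str | Path
) -> None:
    """Write the score-shaded interaction graph.

    ``node_link_json`` and ``graphml`` carry the same payload (gene,
    final_score, shade on nodes; confidence on edges) and round-trip through
    each other.  ``html`` embeds the same graph in a standalone interactive
    SVG page (hover for scores), nodes filled from the blue ramp.
    """
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {format!r} (expected one of {GRAPH_FORMATS})")
    close, stream = _as_output_stream(destination)
    try:
        if format == "node_link_json":
            payload = json_graph.node_link_data(report.graph, edges="edges")
            payload["nodes"].sort(key=lambda n: str(n["id"]).casefold())
            payload["edges"].sort(
                key=lambda e: tuple(sorted((str(e["source"]).casefold(), str(e["target"]).casefold())))
            )
            json.dump(payload, stream, indent=2, sort_keys=True)
            stream.write("\n")
        elif format == "graphml":
            for line in nx.generate_graphml(report.graph, named_key_ids=True):
                stream.write(line + "\n")
        else:
            stream.write(render_html(report))
    finally:
        if close:
            stream.close()


def load_graph(source: TextIO | str | Path, format: str) -> nx.Graph:
    """Read back a graph document written by :func:`export_graph`."""
    if format == "node_link_json":
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        else:
            payload = json.load(source)
        return json_graph.node_link_graph(payload, edges="edges")
    if format == "graphml":
        if isinstance(source, (str, Path)):
            graph = nx.read_graphml(source)
        else:
            graph = nx.parse_graphml(source.read())
        # GraphML stores typed attributes; normalize node ids to plain str
        return nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    raise ValueError(f"cannot load graph format {format!r}")


def render_html(report: EnrichmentReport, width: int = 760, height: int = 640) -> str:
    """Render the graph payload as a self-contained HTML/SVG document.

    Node positions come from a deterministic force-directed (spring) layout;
    each node's fill is its shade on the blue ramp and its tooltip carries the
    gene symbol and final score.  No external assets: the file is viewable
    offline.
    """
    graph = report.graph
    if len(graph) == 0:
        raise LitnetError("nothing to export")
    pos = nx.spring_layout(graph, seed=0)
    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    pad = 40

    def sx(x: float) -> float:
        span = (max(xs) - min(xs)) or 1.0
        return pad + (x - min(xs)) / span * (width - 2 * pad)

    def sy(y: float) -> float:
        span = (max(ys) - min(ys)) or 1.0
        return pad + (y - min(ys)) / span * (height - 2 * pad)

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>litnet interaction graph</title>",
        "<style>body{font-family:sans-serif} .node:hover{stroke:#e6550d;stroke-width:3px}</style>",
        "</head><body>",
        f"<h2>Keyword: {report.parameters.get('keyword', '?')}</h2>",
        "<p>Darker blue = higher final score. Hover a node for details; lines are protein–protein interactions.</p>",
        f"<svg width='{width}' height='{height}' xmlns='http://www.w3.org/2000/svg'>",
    ]
    for a, b, data in sorted(
        graph.edges(data=True), key=lambda e: (e[0].casefold(), e[1].casefold())
    ):
        parts.append(
            f"<line x1='{sx(pos[a][0]):.1f}' y1='{sy(pos[a][1]):.1f}' "
            f"x2='{sx(pos[b][0]):.1f}' y2='{sy(pos[b][1]):.1f}' "
            f"stroke='#bbb' stroke-width='{1 + data['confidence'] / 500:.2f}'>"
            f"<title>{a}–{b} confidence {data['confidence']}</title></line>"
        )
    for gene in sorted(graph.nodes, key=str.casefold):
        attrs = graph.nodes[gene]
        parts.append(
            f"<g class='node'><circle cx='{sx(pos[gene][0]):.1f}' cy='{sy(pos[gene][1]):.1f}' r='11' "
            f"fill='{shade_to_color(attrs['shade'])}' stroke='#555'>"
            f"<title>{gene}: final score {attrs['final_score']:.4f}</title></circle>"
            f"<text x='{sx(pos[gene][0]):.1f}' y='{sy(pos[gene][1]) - 14:.1f}' "
            f"text-anchor='middle' font-size='10'>{gene}</text></g>"
        )
    parts += ["</svg>", "</body></html>", ""]
    return "\n".join(parts)


def table_text(report: EnrichmentReport) -> str:
    """The TSV table as a string (convenience for tests and digests)."""
    buf = io.StringIO()
    export_table(report, buf)
    return buf.getvalue()
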