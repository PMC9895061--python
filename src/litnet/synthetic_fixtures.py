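"""Synthetic planted-signal benchmarks for the whole ranking pipeline.

Real inputs for this method are a live literature snapshot and a STRING
network, neither of which is reproducible or shippable.  This module
generates self-contained stand-ins with a known ground truth instead: a gene
list ``G0001..``, a corpus of filler-token abstracts in which the query
keyword is inserted with a controlled per-gene probability, a gene→abstract
map, and a random interaction network.  A chosen subset of *planted* genes
receives elevated keyword prevalence and (optionally) a full interaction
clique; everything else is background.  Recovering the planted genes at the
top of the ranking is the fixture analogue of the known-drug-target
validations the method is used for.

Two deliberate simplifications keep the signal clean:

* the filler vocabulary excludes every keyword token, so background matches
  occur only by explicit insertion and per-class keyword prevalence is
  exactly the configured Bernoulli rate;
* the keyword is inserted at most once per selected abstract — matching is
  abstract-level, so multiplicity would be invisible anyway.

Planted genes are drawn uniformly at random from the list (not the first
*k* names): ranking breaks ties lexicographically, and position-correlated
planting would bias null-calibration checks.

All randomness flows from one integer seed through per-component child
streams, so the corpus and network are independently reproducible and a
bundle serializes byte-identically across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (
    AbstractCorpus,
    AbstractRecord,
    GeneList,
    GenePmidMap,
    read_corpus,
    read_gene_list,
    read_gene_pmid_map,
)
from .ppi_scoring import read_ppi_edges
from .ranking_report import EnrichmentReport, rank_of

import networkx as nx

# Filler vocabulary for abstract bodies: generic molecular-biology prose
# tokens.  Any token colliding with the configured keyword is filtered out at
# generation time.
FILLER_VOCAB = (
    "cell", "protein", "pathway", "expression", "signaling", "tumor",
    "apoptosis", "kinase", "receptor", "binding", "regulation", "analysis",
    "treatment", "response", "growth", "inhibitor", "complex", "membrane",
    "transcription", "mutation", "cancer", "tissue", "assay", "activity",
    "function", "domain", "structure", "metabolism", "proliferation",
    "phosphorylation", "interaction", "mechanism", "induction", "mouse",
    "human", "clinical", "patients", "levels", "results", "study",
    "increased", "decreased", "observed", "measured", "significant",
    "role", "novel", "target", "therapy", "model",
)

DEFAULT_KEYWORD = "reactive oxygen species"


@dataclass(frozen=True)
class FixtureConfig:
    """Generation parameters; defaults give a clearly recoverable signal.

    ``planted_prevalence``/``background_prevalence`` are the per-abstract
    probabilities that a planted/background gene's abstract contains the
    keyword.  ``abstracts_per_gene`` is an int or an inclusive (min, max)
    range.  With ``planted_clique`` the planted genes are fully connected at
    confidence 900; background edges appear independently with probability
    ``background_edge_prob`` at confidence uniform on 400–999.
    """

    n_genes: int = 200
    n_planted: int = 5
    abstracts_per_gene: int | tuple[int, int] = 30
    keyword: str = DEFAULT_KEYWORD
    planted_prevalence: float = 0.5
    background_prevalence: float = 0.02
    planted_clique: bool = True
    background_edge_prob: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append(f"n_genes must be positive, got {self.n_genes}")
        if not 0 <= self.n_planted <= self.n_genes:
            problems.append(f"n_planted must be in [0, n_genes], got {self.n_planted}")
        lo, hi = self._abstract_range()
        if lo < 1 or hi < lo:
            problems.append(f"abstracts_per_gene range invalid: {self.abstracts_per_gene}")
        if not 0.0 <= self.background_prevalence <= self.planted_prevalence <= 1.0:
            problems.append(
                "need 0 <= background_prevalence <= planted_prevalence <= 1, got "
                f"({self.background_prevalence}, {self.planted_prevalence})"
            )
        if not 0.0 <= self.background_edge_prob <= 1.0:
            problems.append(f"background_edge_prob must be a probability, got {self.background_edge_prob}")
        if not self.keyword.strip():
            problems.append("keyword must be non-empty")
        if problems:
            raise ValueError("invalid fixture config: " + "; ".join(problems))

    def _abstract_range(self) -> tuple[int, int]:
        if isinstance(self.abstracts_per_gene, int):
            return self.abstracts_per_gene, self.abstracts_per_gene
        lo, hi = self.abstracts_per_gene
        return int(lo), int(hi)

    def to_json(self) -> str:
        payload = dict(self.__dict__)
        if not isinstance(payload["abstracts_per_gene"], int):
            payload["abstracts_per_gene"] = list(payload["abstracts_per_gene"])
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


@dataclass(frozen=True)
class FixtureBundle:
    """A complete, self-consistent set of pipeline inputs plus ground truth."""

    gene_list: GeneList
    corpus: AbstractCorpus
    pmid_map: GenePmidMap
    network: nx.Graph
    planted: frozenset[str]
    config: FixtureConfig = field(default_factory=FixtureConfig)


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Generate a reproducible bundle from ``config`` (see module docstring)."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_plant = np.random.default_rng(seeds[0])
    rng_corpus = np.random.default_rng(seeds[1])
    rng_net = np.random.default_rng(seeds[2])

    width = max(4, len(str(config.n_genes)))
    symbols = tuple(f"G{i + 1:0{width}d}" for i in range(config.n_genes))
    gene_list = GeneList(symbols)
    planted_idx = np.sort(rng_plant.choice(config.n_genes, size=config.n_planted, replace=False))
    planted = frozenset(symbols[i] for i in planted_idx)

    from .text_mining import normalize_text

    keyword_tokens = normalize_text(config.keyword)
    vocab = np.array([w for w in FILLER_VOCAB if w not in set(keyword_tokens)])
    corpus, mapping = _generate_corpus(config, symbols, planted, vocab, keyword_tokens, rng_corpus)
    network = _generate_network(config, symbols, planted, rng_net)
    pmid_map = GenePmidMap(mapping=mapping, unmapped=frozenset())
    return FixtureBundle(gene_list, corpus, pmid_map, network, planted, config)


_BODY_TOKENS = 30
_TITLE_TOKENS = 3


def _generate_corpus(config, symbols, planted, vocab, keyword_tokens, rng):
    lo, hi = config._abstract_range()
    corpus = AbstractCorpus()
    mapping: dict[str, frozenset[str]] = {}
    keyword_text = " ".join(keyword_tokens)
    pmid = 1_000_000
    for gene in symbols:
        n_abs = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        prevalence = config.planted_prevalence if gene in planted else config.background_prevalence
        tokens = vocab[rng.integers(0, len(vocab), size=(n_abs, _TITLE_TOKENS + _BODY_TOKENS))]
        contains = rng.random(n_abs) < prevalence
        positions = rng.integers(0, _BODY_TOKENS + 1, size=n_abs)
        ids = []
        for j in range(n_abs):
            pmid += 1
            title = " ".join(tokens[j, :_TITLE_TOKENS])
            body_tokens = list(tokens[j, _TITLE_TOKENS:])
            if contains[j]:
                body_tokens.insert(int(positions[j]), keyword_text)
            corpus.add(AbstractRecord(str(pmid), title=title, body=" ".join(body_tokens)))
            ids.append(str(pmid))
        mapping[gene] = frozenset(ids)
    return corpus, mapping


def _generate_network(config, symbols, planted, rng):
    network = nx.Graph()
    network.add_nodes_from(symbols)
    n = len(symbols)
    iu, ju = np.triu_indices(n, k=1)
    is_planted = np.isin(np.arange(n), [symbols.index(g) for g in sorted(planted)])
    both_planted = is_planted[iu] & is_planted[ju]
    # clique pairs are fixed edges; everything else is an independent draw
    background_pool = ~both_planted if config.planted_clique else np.ones_like(both_planted)
    draws = rng.random(len(iu)) < config.background_edge_prob
    confidences = rng.integers(400, 1000, size=len(iu))
    if config.planted_clique:
        for i, j, conf, bg, drawn in zip(iu, ju, confidences, background_pool, draws):
            if not bg:
                network.add_edge(symbols[i], symbols[j], confidence=900)
            elif drawn:
                network.add_edge(symbols[i], symbols[j], confidence=int(conf))
    else:
        for i, j, conf, drawn in zip(iu, ju, confidences, draws):
            if drawn:
                network.add_edge(symbols[i], symbols[j], confidence=int(conf))
    return network


# ---------------------------------------------------------------------------
# Serialization: bundles round-trip through the exact external formats the
# pipeline consumes, so fixtures double as format regression tests.
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "genes": "genes.txt",
    "corpus": "corpus.jsonl",
    "map": "gene_pmid_map.tsv",
    "ppi": "ppi_edges.tsv",
    "planted": "planted.txt",
    "config": "config.json",
}


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle into its external-format input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in BUNDLE_FILES.items()}

    with open(paths["genes"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic gene list\n")
        for s in bundle.gene_list.symbols:
            fh.write(s + "\n")
    from .corpus_io import write_corpus, write_gene_pmid_map

    write_corpus(bundle.corpus, paths["corpus"])
    write_gene_pmid_map(bundle.pmid_map, paths["map"])
    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(
            (tuple(sorted(e)) for e in bundle.network.edges), key=lambda e: (e[0], e[1])
        ):
            fh.write(f"{a}\t{b}\t{bundle.network[a][b]['confidence']}\n")
    with open(paths["planted"], "w", encoding="utf-8") as fh:
        for s in sorted(bundle.planted):
            fh.write(s + "\n")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        fh.write(bundle.config.to_json())
    return paths


def read_bundle(in_dir: str | Path) -> FixtureBundle:
    """Read a serialized bundle back through the ordinary input readers."""
    d = Path(in_dir)
    gene_list = read_gene_list(d / BUNDLE_FILES["genes"])
    corpus = read_corpus(d / BUNDLE_FILES["corpus"], format="jsonl")
    pmid_map = read_gene_pmid_map(d / BUNDLE_FILES["map"], gene_list)
    network = read_ppi_edges(str(d / BUNDLE_FILES["ppi"]), min_confidence=0)
    planted = frozenset((d / BUNDLE_FILES["planted"]).read_text().split())
    raw = json.loads((d / BUNDLE_FILES["config"]).read_text())
    if isinstance(raw.get("abstracts_per_gene"), list):
        raw["abstracts_per_gene"] = tuple(raw["abstracts_per_gene"])
    return FixtureBundle(gene_list, corpus, pmid_map, network, planted, FixtureConfig(**raw))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def rank_bundle(bundle: FixtureBundle, min_confidence: int = 400, top: int | None = None) -> EnrichmentReport:
    """Run the full in-memory pipeline on a bundle and return the report."""
    from .text_mining import Keyword, mine_gene_list, text_scores
    from .ppi_scoring import induced_subgraph, ppi_scores
    from .ranking_report import build_report, top_n

    keyword = Keyword(bundle.config.keyword)
    results = mine_gene_list(bundle.gene_list, keyword, bundle.corpus, bundle.pmid_map)
    text = text_scores(results)
    edges_kept = nx.Graph(
        (a, b, d)
        for a, b, d in bundle.network.edges(data=True)
        if d["confidence"] >= min_confidence
    )
    edges_kept.add_nodes_from(bundle.network.nodes)
    sub = induced_subgraph(edges_kept, bundle.gene_list)
    ppi = ppi_scores(sub)
    report = build_report(
        results,
        text,
        ppi,
        sub,
        parameters={
            "keyword": bundle.config.keyword,
            "min_confidence": min_confidence,
            "seed": bundle.config.seed,
        },
    )
    return top_n(report, top) if top is not None else report


def evaluate_recovery(report: EnrichmentReport, planted: frozenset[str] | set[str], k: int) -> float:
    """Fraction of planted genes ranked within the top ``k`` of the report."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not planted:
        raise ValueError("planted set is empty")
    hits = sum(1 for g in planted if (rank_of(report, g) or float("inf")) <= k)
    return hits / len(planted)
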