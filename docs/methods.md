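# Methods

## The ranking model

`litnet` prioritizes candidate drug targets from a user-supplied list of
differentially expressed genes (DEGs) by combining two per-gene evidence
channels into one additive score:

**Text Score.** For gene *g* with a set of linked PubMed abstracts, let
*R(g)* be the number of those abstracts available in the corpus (the record
number) and *M(g)* the number of them containing the user's keyword phrase
(the match number). The hit ratio is

    h(g) = M(g) / R(g),        h(g) = 0 when R(g) = 0,

and the Text Score is the hit ratio max-normalized over the query list:

    T(g) = h(g) / max_g' h(g')       (all zeros when every h is 0).

**PPI Score.** From a STRING-format edge list thresholded at a minimum
combined confidence (default 400, the conventional medium-confidence
cutoff), the subgraph induced on the query list is built; every query gene
is a node, and edges require both endpoints in the list. With *d(g)* the
degree of *g* in that subgraph,

    P(g) = d(g) / max_g' d(g')       (all zeros in an edgeless subgraph).

**Final score and ranking.** F(g) = T(g) + P(g) ∈ [0, 2]. Genes are ranked
by descending F; ties break by higher T, then case-fold lexicographic
symbol, so ranks are unique, 1-based and fully deterministic. The full list
is always ranked; the top-N table (default 50) is a presentation filter, so
a gene's rank does not depend on N.

The method is a heuristic evidence score, not a statistical test: no
p-values or multiple-testing machinery are attached, and scores are only
comparable within one run (one list, one keyword, one corpus and network).

## Matching rules

Text is normalized by case-folding, mapping punctuation, hyphens and
underscores to spaces, and splitting on whitespace. The keyword is matched
as an exact contiguous token phrase ("reactive-oxygen species" matches
"reactive oxygen species"; "species … oxygen" does not). Matching is
abstract-level: an abstract counts once no matter how often the phrase
repeats — both the numerator and denominator of the hit ratio count
abstracts. There is no stemming and no synonym expansion ("ROS" does not
match "reactive oxygen species"); users who want synonyms should run
alternative keywords and compare rankings. Titles are searched together
with bodies by default (`search_fields="title+abstract"`), matching how
PubMed keyword queries behave; body-only matching is a switch.

## Design choices that were genuinely open

* **Hit-ratio normalization.** Dividing by the list maximum preserves
  zeros, lands on [0, 1], and makes the text channel commensurate with the
  PPI channel before summation. Rank- or z-normalization would decouple the
  score from the actual match ratios and behave badly with heavy zero
  inflation (most genes match a specific keyword never or rarely).
* **PPI Score = max-normalized induced degree.** Counting in-list
  interactions is the minimal reading of "more interactions, higher score".
  Confidences do not weight the degree by default; a weighted-degree mode
  (sum of confidence/1000, then max-normalized) is available
  (`--weight-ppi-by-confidence`).
* **Tie-breaking** (final → text → symbol) is needed for reproducibility;
  any deterministic rule would do, text-score-first favors the literature
  channel, which is the more specific signal.
* **Gene identity** is case-fold symbol equality. No identifier system is
  imposed; an alias/name map can be applied when loading STRING ids
  (`name_map` in `read_ppi_edges`).
* **Record number** counts only mapped abstract ids actually present in the
  corpus; ids referencing absent abstracts are dropped. Genes with no row
  in the mapping file are flagged `unmapped`, distinct from genes mapped to
  an empty set, so reports separate "no literature link" from "no match".

## Parameters

| parameter | default | meaning |
|---|---|---|
| `keyword` | — | word or phrase scanned in abstracts |
| `min_confidence` | 400 | STRING combined_score cutoff (0–1000) |
| `top_n` | 50 | rows kept in the report |
| `search_fields` | title+abstract | text searched per abstract |
| `weight_by_confidence` | off | confidence-weighted PPI degree |

## The synthetic benchmark

Real inputs (a live PubMed snapshot, a STRING release, a study's RNA-seq)
are neither shippable nor stable, so correctness is assessed on generated
fixtures with known ground truth. A bundle holds `n_genes` genes
(`G0001..`), each with `abstracts_per_gene` abstracts of filler tokens; the
keyword phrase is inserted into each abstract independently with
probability `planted_prevalence` for a randomly chosen planted subset and
`background_prevalence` otherwise. The network gives the planted genes a
full clique at confidence 900 (optional) over independent background edges
(`background_edge_prob`, confidence uniform 400–999).

Two properties make the signal analyzable: the filler vocabulary excludes
every keyword token, so per-class keyword prevalence is exactly the
configured Bernoulli rate; and planted genes are drawn uniformly at random
from the list, so the deterministic lexicographic tie-break cannot
correlate with planted status (important for the null check below).

The default configuration — 200 genes, 5 planted, 30 abstracts/gene,
prevalence 0.5 vs 0.02, clique plus background edge probability 0.01 — is
the package's standing benchmark: planted recovery in the top 20, averaged
over 50 seeds, must reach at least 0.95 (measured: 1.0). A null
configuration (equal prevalence 0.05, no clique) over 200 seeds checks
calibration: planted ranks must be consistent with uniform (KS test,
α = 0.01). Problem sizes were chosen so the full property suite runs in a
few minutes on one CPU.

What the fixtures deliberately do **not** model: real abstract language
(word burstiness, keyword co-occurrence with gene names), shared abstracts
between genes, scale-free STRING topology, or hub genes with enormous
literatures. Passing the benchmark shows the pipeline recovers a planted
contrast and does not invent one; it does not validate keyword choice or
literature coverage on real data, which the method's own usage guidance
(compare several keywords) addresses.

## Numerical and degenerate-case conventions

* All-zero hit ratios or an edgeless subgraph yield all-zero scores for
  that channel (no 0/0).
* A gene with zero usable abstracts gets hit ratio 0 plus a
  `zero_records` flag; an isolated gene gets PPI score 0 plus `isolated`.
* Final score equals the sum of its components to better than 1e-12 (it is
  computed as that sum; the bound guards the export path).
* Exports are byte-deterministic: nodes and edges are emitted in sorted
  order, scores print at 6 decimals, the HTML layout uses a fixed
  spring-layout seed, and table footers carry parameters and input digests
  but never timestamps.
* Node shade = F(g) / max F, mapped linearly onto a light-to-dark blue
  ramp; in a truncated report the maximum is taken over the full ranking so
  truncation does not re-shade nodes.

## Remote fetching

`litnet fetch-corpus` talks to NCBI E-utilities (via Biopython's Entrez
client) with polite rate limiting, and caches `corpus.jsonl` +
`gene_pmid_map.tsv`; a warm cache is reused with zero network requests, so
scoring runs are always offline and reproducible. The gene→publication
linkage is a PubMed gene-field symbol query (`SYMBOL[sym]`); this is a
documented choice — gene2pubmed files or other linkages can be supplied
directly as the mapping TSV instead. Abstracts fetched for one gene enter
the shared corpus once; a gene PubMed knows nothing about maps to the empty
set rather than being flagged unmapped.

## Known limitations

* Exact-phrase matching misses abbreviations, inflections and synonyms;
  hit ratios depend on how a field writes about a gene, not only on
  relevance.
* Hit ratios are noisy for genes with few abstracts (a 1/2 outscores a
  40/100); no shrinkage is applied, matching the method's plain-ratio
  definition.
* Degree centrality favors well-studied hub proteins; the confidence
  threshold is the only control.
* Scores have no significance calibration across runs; ranks are the
  interpretable output.
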