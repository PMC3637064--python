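# enrichkit

A gene-set enrichment analysis toolkit with three term-ranking schemes, a
background-calibration engine, library-construction procedures, a
simulated-annealing toroidal grid layout with a clustering significance
index, and sparse nearest-neighbor term networks. Everything runs on
synthetic fixtures — no downloads required.

## What it does

Given an input gene list and a gene-set library (GMT), each library term
is scored three ways:

1. **Fisher exact test** — one-sided upper-tail hypergeometric probability
   of the observed overlap.
2. **Rank-deviation z-score** — the Fisher test has a systematic set-size
   bias, especially for libraries contaminated with unmatchable gene IDs.
   `calibrate_background` runs the Fisher ranking over many random input
   lists to learn each term's expected rank and its standard deviation;
   a term is then scored by the z-score of its observed rank against that
   expectation (negative = earlier than chance).
3. **Combined score** — `c = ln(p) · z`, positive and large for strongly
   enriched terms, sorted descending.

Beyond scoring, the package provides:

- `genesets` — GMT read/write, symbol normalization, library statistics;
- `builders` — library construction from raw resources: per-sample
  expression |z| > 3 sets, protein-interaction hub neighborhoods
  (degree ≥ 120), seed-list expansion through shared network
  intermediates, peak → nearest-TSS top-2000 target sets, 100% IUPAC
  consensus promoter scans (−2000..+500 window), and CuffDiff
  `gene_exp.diff` up/down list extraction;
- `gridviz` — Jaccard term-term similarity (pluggable scorer), simulated
  annealing onto a toroidal grid, and a permutation test for whether
  enriched terms cluster spatially (significant at p < 0.1);
- `termnet` — each top-10 enriched term linked to its most similar other
  top term; JSON/GraphML/TSV export;
- `fixtures` — deterministic synthetic generators for every input format
  (libraries, gene lists, planted enrichment signals, and a toy corpus
  with a ground-truth manifest for all builders).

## CLI

All functionality is exposed through a single `enrichkit` entry point:

```sh
# generate a synthetic workspace (library.gmt, gene_list.txt, toy corpus)
enrichkit simulate --seed 1 --out-dir demo

# calibrate expected Fisher ranks from random lists
enrichkit calibrate --gmt demo/library.gmt --n-lists 1000 \
    --lengths 100 --seed 1 --out demo/background.json

# enrich a gene list (TSV + JSON tables + top-10 bar-graph data)
enrichkit enrich --genes demo/gene_list.txt --gmt demo/library.gmt \
    --background demo/background.json --sort-mode combined --out demo/result

# toroidal grid layout + clustering significance
enrichkit grid --gmt demo/library.gmt --table demo/result.json \
    --seed 1 --out demo/grid.json

# nearest-neighbor network of the top enriched terms
enrichkit network --gmt demo/library.gmt --table demo/result.json \
    --format graphml --out demo/network.graphml

# library builders
enrichkit build expr-z --matrix demo/toy_corpus/expression.tsv --out expr.gmt
enrichkit build ppi-hubs --edges demo/toy_corpus/network.tsv --min-degree 5 --out hubs.gmt
enrichkit build cuffdiff --diff demo/toy_corpus/gene_exp.diff --out-prefix lists

# per-library statistics, ranked by number of terms
enrichkit stats --gmt demo/library.gmt
```

Exit code 2 signals a usage/format problem (with the offending path in the
message); logs go to stderr, data to files. Identical configuration and
seed produce byte-identical artifacts.

## Conventions

- Gene symbols are uppercased and whitespace-stripped; no alias mapping.
- The test universe defaults to the per-library union of member genes and
  can be overridden; input genes outside the universe are dropped from
  the list size n, while set members outside the universe still count
  toward the set size K (they model unmatchable IDs).
- p-value ties rank by larger overlap, then term label; all randomness
  flows from explicit seeds.
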