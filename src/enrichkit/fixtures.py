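"""Deterministic synthetic data for every input the toolkit consumes.

Every generator is a pure function of its parameters plus a seed. One
global seed fans out to independent per-component streams through a fixed
splitting rule — ``SeedSequence(seed, spawn_key=(COMPONENT_ID,))`` with a
frozen integer ID per generator — so adding a new generator never perturbs
the output of an existing one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from enrichkit.builders import Peak, PromoterSequence, TSSRecord
from enrichkit.enrich import InputGeneList
from enrichkit.genesets import GeneSet, GeneSetLibrary, LibraryCategory

__all__ = [
    "FixtureSpec",
    "random_library",
    "noisy_benchmark_library",
    "random_gene_list",
    "planted_enrichment_list",
    "ToyCorpus",
    "toy_corpus",
    "write_toy_corpus",
]

# frozen component IDs for the seed-splitting rule
_CID_LIBRARY = 1
_CID_GENE_LIST = 2
_CID_PLANTED = 3
_CID_TOY_EXPR = 10
_CID_TOY_PPI = 11
_CID_TOY_PEAKS = 12
_CID_TOY_PROMOTERS = 13
_CID_TOY_CUFFDIFF = 14


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


def _universe(size: int) -> list[str]:
    width = max(5, len(str(size)))
    return [f"G{i:0{width}d}" for i in range(1, size + 1)]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a synthetic gene-set library.

    Set sizes are drawn log-uniformly in [size_min, size_max], or — with
    ``distinct_sizes`` — as a permutation of the consecutive sizes
    size_min .. size_min + n_terms - 1 (guaranteeing no two terms share a
    size, which eliminates p-value tie blocks).

    ``noise_fraction`` of each set's genes is replaced by off-universe
    symbols, emulating unmatchable IDs in real libraries. Noise symbols
    are unique per term by default; ``noise_pool_size`` draws them from a
    shared pool instead (unmatchable IDs recur across terms, so they
    inflate set sizes without exploding the population). With
    ``noise_ramp`` the per-term fraction ramps linearly from 0 for the
    first term to ``noise_fraction`` for the last, giving a library whose
    terms are heterogeneously contaminated.
    """

    seed: int = 0
    universe_size: int = 2000
    n_terms: int = 100
    size_min: int = 10
    size_max: int = 200
    noise_fraction: float = 0.0
    noise_pool_size: int | None = None
    noise_ramp: bool = False
    distinct_sizes: bool = False

    def __post_init__(self) -> None:
        if min(self.universe_size, self.n_terms, self.size_min, self.size_max) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must lie in [0, 1)")
        if self.size_min > self.size_max:
            raise ValueError("size_min must not exceed size_max")
        if self.size_max > self.universe_size:
            raise ValueError("set size may not exceed the universe size")
        if self.noise_pool_size is not None and self.noise_pool_size < 1:
            raise ValueError("noise_pool_size must be positive")
        if self.distinct_sizes and self.size_min + self.n_terms - 1 > self.universe_size:
            raise ValueError("distinct sizes exceed the universe size")


def random_library(spec: FixtureSpec, name: str = "fixture") -> GeneSetLibrary:
    """Generate a random gene-set library per the spec (reproducible)."""
    rng = _rng(spec.seed, _CID_LIBRARY)
    genes = _universe(spec.universe_size)
    if spec.distinct_sizes:
        sizes = rng.permutation(
            np.arange(spec.size_min, spec.size_min + spec.n_terms)
        )
    else:
        sizes = np.exp(
            rng.uniform(
                math.log(spec.size_min), math.log(spec.size_max + 1), spec.n_terms
            )
        ).astype(int)
        sizes = np.clip(sizes, spec.size_min, spec.size_max)
    library = GeneSetLibrary(
        name=name,
        category=LibraryCategory.MISCELLANEOUS,
        universe=genes if spec.noise_fraction > 0 else None,
    )
    pool = (
        [f"NOISE{i:06d}" for i in range(1, spec.noise_pool_size + 1)]
        if spec.noise_pool_size is not None
        else None
    )
    noise_counter = 0
    denom = max(spec.n_terms - 1, 1)
    for t in range(spec.n_terms):
        size = int(sizes[t])
        frac = (
            spec.noise_fraction * t / denom if spec.noise_ramp else spec.noise_fraction
        )
        n_noise = int(math.ceil(frac * size))
        n_real = size - n_noise
        picked = rng.choice(spec.universe_size, size=max(n_real, 1), replace=False)
        members = {genes[i] for i in picked}
        if pool is not None:
            jdx = rng.choice(len(pool), size=min(n_noise, len(pool)), replace=False)
            members |= {pool[j] for j in jdx}
        else:
            for _ in range(n_noise):
                noise_counter += 1
                members.add(f"NOISE{noise_counter:06d}")
        library.add(GeneSet(term=f"TERM{t + 1:04d}", genes=frozenset(members)))
    return library


def noisy_benchmark_library(
    seed: int = 0,
    universe_size: int = 2500,
    noise_pool_size: int = 2500,
    n_terms: int = 300,
    real_size_min: int = 300,
    real_size_max: int = 900,
    max_noise_fraction: float = 0.75,
    name: str = "noisy_benchmark",
) -> GeneSetLibrary:
    """A benchmark library with heterogeneously contaminated terms.

    Each term's *matchable* gene count is log-uniform in
    [real_size_min, real_size_max]; on top of that, unmatchable symbols
    from a shared off-universe pool are added so that the noise fraction
    ramps linearly from 0 (first term) to ``max_noise_fraction`` (last
    term). Heavily contaminated terms are chronically under-ranked by the
    plain overlap test — the situation rank calibration corrects.
    """
    if not (0 <= max_noise_fraction < 1):
        raise ValueError("max_noise_fraction must lie in [0, 1)")
    rng = _rng(seed, _CID_LIBRARY)
    genes = _universe(universe_size)
    pool = [f"NOISE{i:06d}" for i in range(1, noise_pool_size + 1)]
    reals = np.exp(
        rng.uniform(math.log(real_size_min), math.log(real_size_max + 1), n_terms)
    ).astype(int)
    library = GeneSetLibrary(
        name=name, category=LibraryCategory.MISCELLANEOUS, universe=genes
    )
    denom = max(n_terms - 1, 1)
    for t in range(n_terms):
        frac = max_noise_fraction * t / denom
        n_real = int(reals[t])
        n_noise = min(int(round(frac / (1 - frac) * n_real)), noise_pool_size)
        idx = rng.choice(universe_size, size=n_real, replace=False)
        members = {genes[i] for i in idx}
        if n_noise:
            jdx = rng.choice(noise_pool_size, size=n_noise, replace=False)
            members |= {pool[j] for j in jdx}
        library.add(GeneSet(term=f"TERM{t + 1:04d}", genes=frozenset(members)))
    return library


def random_gene_list(
    universe: Iterable[str], length: int, seed: int = 0, description: str = ""
) -> InputGeneList:
    """Uniform sample of genes without replacement (reproducible)."""
    pool = sorted(universe)
    if not (1 <= length <= len(pool)):
        raise ValueError(f"length must lie in [1, {len(pool)}], got {length}")
    rng = _rng(seed, _CID_GENE_LIST)
    idx = rng.choice(len(pool), size=length, replace=False)
    return InputGeneList(
        genes=frozenset(pool[i] for i in idx), description=description
    )


def planted_enrichment_list(
    library: GeneSetLibrary,
    target_term: str,
    overlap_fraction: float,
    length: int,
    seed: int = 0,
    universe: Iterable[str] | None = None,
) -> InputGeneList:
    """A labeled input list with a planted signal for one library term.

    ``ceil(overlap_fraction * length)`` genes come from the target term's
    set (restricted to the universe — noise symbols cannot appear in a
    real input list) and the remainder are drawn uniformly from the
    universe minus the term's genes.
    """
    if target_term not in library:
        raise ValueError(f"term {target_term!r} not in library")
    if not (0 < overlap_fraction <= 1):
        raise ValueError("overlap_fraction must lie in (0, 1]")
    uni = frozenset(universe) if universe is not None else library.universe
    term_genes = sorted(library[target_term].genes & uni)
    if not term_genes:
        raise ValueError(f"term {target_term!r} has no genes in the universe")
    rng = _rng(seed, _CID_PLANTED)
    n_signal = min(math.ceil(overlap_fraction * length), len(term_genes), length)
    signal = rng.choice(len(term_genes), size=n_signal, replace=False)
    picked = {term_genes[i] for i in signal}
    filler_pool = sorted(uni - library[target_term].genes)
    n_filler = length - n_signal
    if n_filler > len(filler_pool):
        raise ValueError("universe too small for the requested list length")
    if n_filler:
        idx = rng.choice(len(filler_pool), size=n_filler, replace=False)
        picked |= {filler_pool[i] for i in idx}
    return InputGeneList(
        genes=frozenset(picked),
        description=f"planted:{target_term}",
        label=target_term,
    )


# ---------------------------------------------------------------------------
# Toy corpus for the builders


@dataclass
class ToyCorpus:
    """Small synthetic inputs for every builder, with ground truth.

    ``manifest`` records the planted facts: expression outliers, hub
    nodes, nearest peak-target genes, motif-hit genes, and CuffDiff
    up/down gene lists.
    """

    expression: pd.DataFrame
    network: nx.Graph
    peaks: dict[str, list[Peak]]
    tss: list[TSSRecord]
    promoters: list[PromoterSequence]
    motif: str
    cuffdiff: pd.DataFrame
    manifest: dict
    seed: int


def _toy_expression(seed: int) -> tuple[pd.DataFrame, dict]:
    rng = _rng(seed, _CID_TOY_EXPR)
    # 12 samples: a population z-score is bounded by sqrt(n-1), so |z| > 3
    # needs n >= 11; a single extreme spike then reaches z ~ sqrt(11) = 3.32
    samples = [f"CELL{j}" for j in range(1, 13)]
    genes = [f"EG{i:03d}" for i in range(1, 31)]
    values = rng.normal(10.0, 1.0, size=(len(genes), len(samples)))
    # plant an extreme outlier: one gene spikes in one sample
    outlier_gene, outlier_sample = genes[4], samples[2]
    values[4, :] = 10.0 + rng.normal(0, 0.05, len(samples))
    values[4, 2] = 60.0
    rows = list(genes)
    mat = values
    # a duplicate probe pair for one gene: near-constant + strong-outlier rows
    dup_gene = "EGDUP"
    weak = 10.0 + rng.normal(0, 0.05, len(samples))
    strong = weak.copy()
    strong[5] = 55.0
    rows += [dup_gene, dup_gene]
    mat = np.vstack([mat, weak, strong])
    df = pd.DataFrame(mat, index=rows, columns=samples)
    manifest = {
        "outlier_gene": outlier_gene,
        "outlier_sample": outlier_sample,
        "duplicate_probe_gene": dup_gene,
        "duplicate_probe_sample": samples[5],
    }
    return df, manifest


def _toy_network(seed: int) -> tuple[nx.Graph, dict]:
    rng = _rng(seed, _CID_TOY_PPI)
    g = nx.Graph()
    others = [f"PG{i:03d}" for i in range(1, 21)]
    hub_a, hub_b = "HUBA", "HUBB"
    nbrs_a = others[:5]
    nbrs_b = others[4:10]
    g.add_edges_from((hub_a, n) for n in nbrs_a)
    g.add_edges_from((hub_b, n) for n in nbrs_b)
    # background edges keep everyone else below the hub threshold
    for i in range(10, 19):
        g.add_edge(others[i], others[(i + 1) % 20])
    # seed-expansion ground truth: BRIDGE touches both seeds, LONER only one
    seeds = [nbrs_a[0], nbrs_b[5]]
    g.add_edge("BRIDGE", seeds[0])
    g.add_edge("BRIDGE", seeds[1])
    g.add_edge("LONER", seeds[0])
    manifest = {
        "hub_threshold": 5,
        "hubs": {hub_a: sorted(nbrs_a), hub_b: sorted(nbrs_b)},
        "seed_expansion": {
            "seeds": sorted(seeds),
            "expanded": sorted(set(seeds) | {"BRIDGE"}),
        },
    }
    return g, manifest


def _toy_peaks(seed: int) -> tuple[dict[str, list[Peak]], list[TSSRecord], dict]:
    tss = [
        TSSRecord("TG1", "chr1", 1000),
        TSSRecord("TG2", "chr1", 50000),
        TSSRecord("TG3", "chr2", 2000),
        TSSRecord("TG4", "chr2", 90000),
    ]
    peaks = {
        "EXP1": [
            Peak("chr1", 980, 1020),      # mid 1000 -> TG1, distance 0
            Peak("chr1", 44990, 45010),   # mid 45000 -> TG2, distance 5000
            Peak("chr2", 2150, 2250),     # mid 2200 -> TG3, distance 200
        ]
    }
    manifest = {
        "experiment": "EXP1",
        "nearest": {"TG1": 0.0, "TG2": 5000.0, "TG3": 200.0},
        "top2": ["TG1", "TG3"],
    }
    return peaks, tss, manifest


def _toy_promoters(seed: int) -> tuple[list[PromoterSequence], str, dict]:
    rng = _rng(seed, _CID_TOY_PROMOTERS)
    motif = "CACGTG"
    bases = np.array(list("ACGT"))
    length = 2500  # covers [-2000, +500)

    def random_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    def without_motif(n: int) -> str:
        while True:
            s = random_seq(n)
            if motif not in s and _revcomp(motif) not in s:
                return s

    hit_pos = 1900  # TSS-relative -100
    s1 = without_motif(length)
    s1 = s1[:hit_pos] + motif + s1[hit_pos + len(motif):]
    s2 = without_motif(length)  # no hit
    # reverse-strand hit at window position +100 (index 2100)
    s3 = without_motif(length)
    s3 = s3[:2100] + _revcomp(motif) + s3[2100 + len(motif):]
    # hit OUTSIDE the scanned window: sequence extends to +1000, motif at +800
    s4 = without_motif(3000)
    s4 = s4[:2800] + motif + s4[2800 + len(motif):]
    promoters = [
        PromoterSequence("PR1", s1, offset=-2000),
        PromoterSequence("PR2", s2, offset=-2000),
        PromoterSequence("PR3", s3, offset=-2000),
        PromoterSequence("PR4", s4, offset=-2000),
    ]
    manifest = {"motif": motif, "hits": ["PR1", "PR3"], "window": [-2000, 500]}
    return promoters, motif, manifest


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _toy_cuffdiff(seed: int) -> tuple[pd.DataFrame, dict]:
    rows = []

    def row(gene, v1, v2, lfc, sig):
        return {
            "test_id": gene,
            "gene_id": gene,
            "gene": gene,
            "locus": "chr1:1-2",
            "sample_1": "q1",
            "sample_2": "q2",
            "status": "OK",
            "value_1": v1,
            "value_2": v2,
            "log2(fold_change)": lfc,
            "test_stat": 1.0,
            "p_value": 0.001 if sig == "yes" else 0.5,
            "q_value": 0.01 if sig == "yes" else 0.9,
            "significant": sig,
        }

    rows += [row(f"UP{i}", 1.0, 4.0, 2.0, "yes") for i in range(1, 4)]
    rows += [row(f"DN{i}", 4.0, 1.0, -2.0, "yes") for i in range(1, 3)]
    rows += [row(f"NS{i}", 2.0, 2.1, 0.07, "no") for i in range(1, 5)]
    df = pd.DataFrame(rows)
    manifest = {
        "up": sorted(f"UP{i}" for i in range(1, 4)),
        "down": sorted(f"DN{i}" for i in range(1, 3)),
        "n_up": 3,
        "n_down": 2,
    }
    return df, manifest


def toy_corpus(seed: int = 0) -> ToyCorpus:
    """Generate the full toy corpus with a ground-truth manifest."""
    expr, m_expr = _toy_expression(seed)
    net, m_net = _toy_network(seed)
    peaks, tss, m_peaks = _toy_peaks(seed)
    promoters, motif, m_prom = _toy_promoters(seed)
    cuff, m_cuff = _toy_cuffdiff(seed)
    manifest = {
        "seed": seed,
        "expression": m_expr,
        "network": m_net,
        "peaks": m_peaks,
        "promoters": m_prom,
        "cuffdiff": m_cuff,
    }
    return ToyCorpus(
        expression=expr,
        network=net,
        peaks=peaks,
        tss=tss,
        promoters=promoters,
        motif=motif,
        cuffdiff=cuff,
        manifest=manifest,
        seed=seed,
    )


def write_toy_corpus(corpus: ToyCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write every corpus component in its standard text format.

    Expression/TSS/edge lists as TSV, peaks as BED, promoters as FASTA,
    the differential table in the CuffDiff dialect, and the manifest as
    JSON. Returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "expression.tsv"
    corpus.expression.to_csv(p, sep="\t", index_label="gene")
    paths["expression"] = p

    p = out / "network.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(e)) for e in corpus.network.edges):
            fh.write(f"{a}\t{b}\n")
    paths["network"] = p

    for exp, peaks in corpus.peaks.items():
        p = out / f"peaks_{exp}.bed"
        with open(p, "w", encoding="utf-8") as fh:
            for pk in peaks:
                fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\n")
        paths[f"peaks_{exp}"] = p

    p = out / "tss.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for r in corpus.tss:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.tss}\t{r.strand}\n")
    paths["tss"] = p

    p = out / "promoters.fasta"
    with open(p, "w", encoding="utf-8") as fh:
        for prom in corpus.promoters:
            fh.write(f">{prom.gene} offset={prom.offset}\n")
            for i in range(0, len(prom.sequence), 80):
                fh.write(prom.sequence[i : i + 80] + "\n")
    paths["promoters"] = p

    p = out / "gene_exp.diff"
    corpus.cuffdiff.to_csv(p, sep="\t", index=False)
    paths["cuffdiff"] = p

    p = out / "manifest.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(corpus.manifest, fh, indent=1)
    paths["manifest"] = p
    return paths
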