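"""Gene-set library construction procedures.

Six ways of turning raw resources into gene-set libraries or input lists:

- per-sample expression z-score sets (|z| > 3 by default);
- protein-interaction hub neighborhoods (degree >= 120 by default);
- seed-list expansion through shared network intermediates;
- genomic peak -> nearest-TSS target sets (top 2000 genes by default);
- exact IUPAC consensus scans of promoter windows (-2000..+500);
- up/down gene-list extraction from CuffDiff differential tables.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from enrichkit.genesets import (
    GeneSet,
    GeneSetLibrary,
    LibraryCategory,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "TSSRecord",
    "ConsensusMotif",
    "PromoterSequence",
    "expression_zscore_sets",
    "ppi_hub_sets",
    "seed_expansion_sets",
    "peaks_to_target_sets",
    "consensus_promoter_scan",
    "cuffdiff_extract",
    "read_bed",
    "read_tss_table",
    "read_fasta_promoters",
    "IUPAC",
]


# ---------------------------------------------------------------------------
# Expression z-score sets


def expression_zscore_sets(
    matrix: pd.DataFrame,
    threshold: float = 3.0,
    ddof: int = 0,
    name: str = "expression_zscores",
) -> GeneSetLibrary:
    """Per-sample sets of genes with extreme expression z-scores.

    Rows are genes (duplicate probe rows allowed), columns are samples.
    Each gene row is z-scored against its own mean/sd across samples;
    duplicate probes of one symbol are merged by keeping the entry with
    the highest absolute z per sample. Each sample becomes a term whose
    gene set holds the genes with |z| > ``threshold`` in that sample.
    Constant rows (sd = 0) are skipped with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to compute z-scores")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("%d constant rows skipped (sd = 0)", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    symbols = [normalize_symbol(str(g)) for g in matrix.index]
    # merge duplicate probes: keep the max-|z| entry per (gene, sample)
    merged: dict[str, np.ndarray] = {}
    for row, sym in enumerate(symbols):
        if constant[row]:
            continue
        zr = z[row]
        if sym not in merged:
            merged[sym] = zr.copy()
        else:
            prev = merged[sym]
            take = np.abs(zr) > np.abs(prev)
            prev[take] = zr[take]
    library = GeneSetLibrary(name=name, category=LibraryCategory.CELL_TYPES)
    for j, sample in enumerate(matrix.columns):
        genes = frozenset(
            sym for sym, zr in merged.items() if abs(zr[j]) > threshold
        )
        if genes:
            library.add(GeneSet(term=str(sample), genes=genes))
    return library


# ---------------------------------------------------------------------------
# PPI hubs and seed expansion


def _check_network(network: nx.Graph) -> None:
    if any(network.has_edge(v, v) for v in network):
        raise ValueError("interaction network must not contain self-loops")


def ppi_hub_sets(
    network: nx.Graph, min_degree: int = 120, name: str = "ppi_hubs"
) -> GeneSetLibrary:
    """Hub neighborhoods: every node with degree >= ``min_degree``
    (inclusive) becomes a term whose gene set is its direct neighbors."""
    _check_network(network)
    library = GeneSetLibrary(name=name, category=LibraryCategory.PATHWAYS)
    for node in sorted(network.nodes):
        if network.degree(node) >= min_degree:
            library.add(
                GeneSet(
                    term=str(node),
                    genes=frozenset(str(n) for n in network.neighbors(node)),
                )
            )
    return library


def seed_expansion_sets(
    seed_lists: Mapping[str, Iterable[str]],
    network: nx.Graph,
    name: str = "seed_expanded",
) -> GeneSetLibrary:
    """Expand each seed gene list with network intermediates.

    The expanded set is the seeds plus every non-seed node adjacent to at
    least two distinct seeds (one-intermediate paths between seed pairs).
    Seeds absent from the network stay in the output set but contribute no
    paths (logged).
    """
    _check_network(network)
    library = GeneSetLibrary(name=name, category=LibraryCategory.DISEASES_DRUGS)
    node_set = {normalize_symbol(str(v)): v for v in network.nodes}
    for term, seeds in seed_lists.items():
        seed_syms = {normalize_symbol(s) for s in seeds}
        absent = seed_syms - node_set.keys()
        if absent:
            logger.info(
                "term %r: %d seeds absent from the network", term, len(absent)
            )
        counts: dict[str, int] = {}
        for s in seed_syms & node_set.keys():
            for nbr in network.neighbors(node_set[s]):
                sym = normalize_symbol(str(nbr))
                if sym not in seed_syms:
                    counts[sym] = counts.get(sym, 0) + 1
        expanded = seed_syms | {v for v, c in counts.items() if c >= 2}
        library.add(GeneSet(term=term, genes=frozenset(expanded)))
    return library


# ---------------------------------------------------------------------------
# Peaks -> nearest-TSS target sets


@dataclass(frozen=True)
class Peak:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"require start < end, got {self}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site of a gene (1-based position)."""

    gene: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_bed(source: IO[str] | str, label: str = "") -> list[Peak]:
    """Parse a minimal BED (chrom, start, end) into peaks."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_bed(fh, label)
    peaks = []
    for line in source:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        peaks.append(Peak(chrom=f[0], start=int(f[1]), end=int(f[2])))
    return peaks


def read_tss_table(source: IO[str] | str) -> list[TSSRecord]:
    """Parse a TSV with columns gene, chrom, tss, strand."""
    df = pd.read_csv(source, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ValueError(f"TSS table missing required column {col!r}")
    records = [
        TSSRecord(
            gene=normalize_symbol(r.gene),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]
    if len({(r.gene, r.tss) for r in records}) != len(records):
        raise ValueError("duplicate (gene, tss) records in TSS table")
    return records


def peaks_to_target_sets(
    peaks_by_experiment: Mapping[str, Sequence[Peak]],
    tss: Sequence[TSSRecord],
    top_n: int = 2000,
    name: str = "peak_targets",
) -> GeneSetLibrary:
    """Top-N nearest-gene target sets per peak experiment.

    Every peak is assigned the gene with the nearest TSS on the same
    chromosome (absolute distance from the peak midpoint). Genes are then
    ranked by their minimal peak distance and the first ``top_n`` distinct
    genes form the experiment's set. Equidistant TSS ties go to the
    upstream gene (TSS <= midpoint), then lexicographically.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    library = GeneSetLibrary(name=name, category=LibraryCategory.TRANSCRIPTION)
    for experiment, peaks in peaks_by_experiment.items():
        best: dict[str, float] = {}
        matched = False
        for peak in peaks:
            candidates = by_chrom.get(peak.chrom)
            if not candidates:
                continue
            matched = True
            mid = peak.midpoint
            rec = min(
                candidates,
                key=lambda r: (abs(r.tss - mid), 0 if r.tss <= mid else 1, r.gene),
            )
            d = abs(rec.tss - mid)
            if rec.gene not in best or d < best[rec.gene]:
                best[rec.gene] = d
        if not matched:
            logger.warning(
                "experiment %r: no peaks share a chromosome with the TSS "
                "annotation; empty set skipped",
                experiment,
            )
            continue
        ordered = sorted(best, key=lambda g: (best[g], g))
        library.add(GeneSet(term=experiment, genes=frozenset(ordered[:top_n])))
    return library


# ---------------------------------------------------------------------------
# Consensus promoter scan

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class ConsensusMotif:
    """An IUPAC degenerate nucleotide consensus string."""

    sequence: str
    label: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set(IUPAC)
        if bad or not seq:
            raise ValueError(f"invalid IUPAC characters: {sorted(bad) or 'empty'}")
        object.__setattr__(self, "sequence", seq)

    def regex(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in self.sequence))

    def reverse_complement(self) -> "ConsensusMotif":
        rc = self.sequence.translate(_COMPLEMENT)[::-1]
        return ConsensusMotif(sequence=rc, label=self.label)


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter sequence with the TSS-relative offset of its first base
    (offset -2000 means the sequence starts 2000 bp upstream of the TSS)."""

    gene: str
    sequence: str
    offset: int = -2000

    def window(self, start: int, end: int) -> str:
        """Subsequence covering TSS-relative [start, end); clipped to the
        available sequence."""
        i = max(0, start - self.offset)
        j = max(0, end - self.offset)
        return self.sequence[i:j].upper()


def read_fasta_promoters(
    source: IO[str] | str, offset: int = -2000
) -> list[PromoterSequence]:
    """Parse promoter FASTA; record IDs are gene symbols."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_fasta_promoters(fh, offset)
    out: list[PromoterSequence] = []
    gene, chunks = None, []
    for line in source:
        line = line.strip()
        if line.startswith(">"):
            if gene is not None:
                out.append(PromoterSequence(gene, "".join(chunks), offset))
            gene, chunks = normalize_symbol(line[1:].split()[0]), []
        elif line:
            chunks.append(line)
    if gene is not None:
        out.append(PromoterSequence(gene, "".join(chunks), offset))
    return out


def consensus_promoter_scan(
    promoters: Sequence[PromoterSequence],
    motif: ConsensusMotif,
    window: tuple[int, int] = (-2000, 500),
) -> GeneSet:
    """Genes whose promoter window holds >= 1 exact consensus match.

    The TSS-relative window (default -2000..+500) is scanned on both
    strands; only 100% IUPAC-compatible matches count. Sequences shorter
    than the window are scanned as-is with a warning.
    """
    start, end = window
    if start >= end:
        raise ValueError("window start must precede window end")
    fwd = motif.regex()
    rev = motif.reverse_complement().regex()
    hits = set()
    for prom in promoters:
        seq = prom.window(start, end)
        if len(seq) < (end - start):
            logger.warning(
                "promoter %s shorter than the scan window (%d < %d); "
                "scanned as-is",
                prom.gene,
                len(seq),
                end - start,
            )
        if not seq:
            continue
        if fwd.search(seq) or rev.search(seq):
            hits.add(prom.gene)
    return GeneSet(
        term=motif.label or motif.sequence,
        description=f"consensus {motif.sequence} in [{start},{end})",
        genes=frozenset(hits),
    )


# ---------------------------------------------------------------------------
# CuffDiff extraction

CUFFDIFF_COLUMNS = [
    "test_id", "gene_id", "gene", "locus", "sample_1", "sample_2",
    "status", "value_1", "value_2", "log2(fold_change)", "test_stat",
    "p_value", "q_value", "significant",
]


def cuffdiff_extract(
    source: IO[str] | str | pd.DataFrame,
    direction: str = "both",
) -> dict[str, frozenset[str]]:
    """Extract up/down gene lists from a CuffDiff ``gene_exp.diff`` table.

    Rows flagged ``significant == "yes"`` are split by the sign of
    log2(fold_change); symbols are normalized and deduplicated. Returns
    {"up": genes, "down": genes} (keys filtered by ``direction``); either
    set may be empty. Wrap non-empty results in
    :class:`~enrichkit.enrich.InputGeneList` for enrichment.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t")
    for col in ("gene", "log2(fold_change)", "significant", "value_1", "value_2"):
        if col not in df.columns:
            raise ValueError(f"CuffDiff table missing required column {col!r}")
    sig = df[df["significant"].astype(str).str.lower() == "yes"]
    lfc = pd.to_numeric(sig["log2(fold_change)"], errors="coerce")

    def genes_of(mask) -> frozenset[str]:
        out = set()
        for g in sig.loc[mask, "gene"].astype(str):
            for part in g.split(","):  # CuffDiff comma-joins loci gene names
                part = part.strip()
                if part and part != "-":
                    out.add(normalize_symbol(part))
        return frozenset(out)

    result: dict[str, frozenset[str]] = {}
    if direction in ("up", "both"):
        result["up"] = genes_of(lfc > 0)
    if direction in ("down", "both"):
        result["down"] = genes_of(lfc < 0)
    return result
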