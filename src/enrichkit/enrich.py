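"""Enrichment scoring: Fisher exact test, rank-deviation z-score, combined score.

Three ways to rank the terms of a gene-set library against an input gene
list:

1. the one-sided Fisher exact test (upper-tail hypergeometric probability
   of the observed overlap);
2. a correction that scores each term by the z-score of its Fisher rank
   against the mean/sd rank observed over many random input lists
   (the *rank-deviation* method — small/negative z means the term ranked
   much earlier than it does by chance);
3. a combined score ``c = ln(p) * z`` which, under the sign convention
   used here, is large and positive for strongly enriched terms.

The random-list calibration lives in :func:`calibrate_background`; the
resulting :class:`RankBackground` is a lookup table of per-term expected
ranks stratified by input-list length.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from enrichkit.genesets import GeneSetLibrary, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "P_FLOOR",
    "SORT_MODES",
    "InputGeneList",
    "ContingencyCounts",
    "RankBackground",
    "EnrichmentRecord",
    "EnrichmentTable",
    "LibraryIndex",
    "fisher_exact_p",
    "rank_by_p",
    "calibrate_background",
    "rank_zscore",
    "combined_score",
    "enrich",
    "benchmark_rank_recovery",
    "BenchmarkResult",
]

#: p-values are clamped to at least this before taking logs.
P_FLOOR = 1e-300

SORT_MODES = ("p_value", "z_score", "combined")


@dataclass(frozen=True)
class InputGeneList:
    """A user gene list. ``label`` optionally names the term expected to
    rank highly (used by the benchmark harness)."""

    genes: frozenset[str]
    description: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )
        if not self.genes:
            raise ValueError("input gene list is empty")

    @classmethod
    def from_text(cls, text: str, description: str = "") -> "InputGeneList":
        """Parse a newline-separated list of gene symbols."""
        genes = [ln.strip() for ln in text.splitlines() if ln.strip()]
        return cls(genes=frozenset(genes), description=description)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ContingencyCounts:
    """Hypergeometric test inputs: overlap k, list size n, set size K,
    universe size N."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"require 0 <= k <= min(n, K); got {self}")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"require K <= N and n <= N; got {self}")
        if self.N < 1:
            raise ValueError("universe must be non-empty")


def fisher_exact_p(counts: ContingencyCounts) -> float:
    """One-sided upper-tail Fisher exact test: P(X >= k) with
    X ~ Hypergeometric(N, K, n). Returns a value in (0, 1]."""
    p = float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))
    return min(max(p, P_FLOOR), 1.0)


def combined_score(p: float, z: float) -> float:
    """Combined enrichment score ``c = ln(p) * z``.

    With z = (observed rank - expected rank)/sd, enriched terms have small
    p and negative z, so c is large and positive; tables sort c descending.
    p is clamped to >= 1e-300 so the score stays finite.
    """
    if not p > 0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p > 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return math.log(max(p, P_FLOOR)) * z


def rank_zscore(observed_rank: int, term_background: tuple[float, float]) -> float:
    """z-score of an observed Fisher rank against its expected (mean, sd)
    rank under random input lists. Negative = earlier than expected."""
    mean_rank, sd_rank = term_background
    if observed_rank < 1:
        raise ValueError("ranks are 1-based positive integers")
    if not sd_rank > 0:
        raise ValueError(
            "sd_rank must be > 0 (terms with degenerate rank variance "
            "cannot be z-scored; fall back to p-value ordering)"
        )
    return (observed_rank - mean_rank) / sd_rank


class LibraryIndex:
    """Vectorized scoring index over a library.

    The test population is ``universe ∪ (all library genes)``: gene IDs
    that appear in sets but not in the supplied universe ("noise" symbols
    that no input list can match) still count toward set sizes K and the
    population N. Input genes outside the universe are dropped from n.
    """

    def __init__(self, library: GeneSetLibrary, universe: Iterable[str] | None = None):
        if len(library) == 0:
            raise ValueError("library is empty")
        self.library = library
        self.terms: list[str] = library.terms
        lib_union: set[str] = set()
        for gs in library:
            lib_union |= gs.genes
        uni = (
            frozenset(normalize_symbol(g) for g in universe)
            if universe is not None
            else library.universe
        )
        self.universe: frozenset[str] = uni
        self.N: int = len(uni | lib_union)
        genes_sorted = sorted(uni)
        self._col: dict[str, int] = {g: i for i, g in enumerate(genes_sorted)}
        n_terms, n_genes = len(self.terms), len(genes_sorted)
        M = np.zeros((n_terms, n_genes), dtype=np.float64)
        for t, gs in enumerate(library):
            for g in gs.genes:
                j = self._col.get(g)
                if j is not None:
                    M[t, j] = 1.0
        self._M = M
        self.K = np.array([len(gs) for gs in library], dtype=np.int64)
        # deterministic tiebreak: lexicographic order of term labels
        self._lex = np.argsort(np.argsort(np.array(self.terms)))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def _input_vector(self, genes: frozenset[str]) -> tuple[np.ndarray, int]:
        cols = [self._col[g] for g in genes if g in self._col]
        v = np.zeros(self._M.shape[1], dtype=np.float64)
        v[cols] = 1.0
        return v, len(cols)

    def overlaps(self, input_list: InputGeneList) -> tuple[np.ndarray, int]:
        """Per-term overlap counts k and the universe-restricted list size n."""
        v, n = self._input_vector(input_list.genes)
        dropped = len(input_list.genes) - n
        if dropped:
            logger.info(
                "%d input genes outside the universe dropped from n", dropped
            )
        k = (self._M @ v).astype(np.int64)
        return k, n

    def pvalues(self, k: np.ndarray, n: int) -> np.ndarray:
        """Vectorized upper-tail hypergeometric p-values, floored/capped."""
        p = hypergeom.sf(k - 1, self.N, self.K, n)
        return np.clip(p, P_FLOOR, 1.0)

    def ranks(self, p: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Competition-free total ranking 1..n_terms: ascending p, ties by
        larger overlap k then lexicographic term label."""
        order = np.lexsort((self._lex, -k, p))
        ranks = np.empty(len(p), dtype=np.int64)
        ranks[order] = np.arange(1, len(p) + 1)
        return ranks

    def rank_matrix(self, lists: np.ndarray, n: int) -> np.ndarray:
        """Fisher ranks for many same-length input lists.

        ``lists`` is an (n_lists, n) integer array of universe column
        indices. Returns an (n_lists, n_terms) rank matrix.
        """
        n_lists = lists.shape[0]
        B = np.zeros((self._M.shape[1], n_lists), dtype=np.float64)
        B[lists.T, np.arange(n_lists)[None, :].repeat(lists.shape[1], axis=0)] = 1.0
        Kmat = (self._M @ B).astype(np.int64)  # n_terms x n_lists
        P = hypergeom.sf(Kmat - 1, self.N, self.K[:, None], n)
        P = np.clip(P, P_FLOOR, 1.0)
        out = np.empty((n_lists, self.n_terms), dtype=np.int64)
        for j in range(n_lists):
            out[j] = self.ranks(P[:, j], Kmat[:, j])
        return out


def rank_by_p(
    library: GeneSetLibrary,
    input_list: InputGeneList,
    universe: Iterable[str] | None = None,
) -> list[tuple[str, float, int]]:
    """Rank all library terms by Fisher p-value.

    Returns ``[(term, p_value, rank), ...]`` in library order. Raises if
    the input list has no genes in the universe.
    """
    idx = LibraryIndex(library, universe)
    k, n = idx.overlaps(input_list)
    if n == 0:
        raise ValueError(
            "no input genes found in the universe; check that the gene "
            "list and the library/universe use the same symbol space"
        )
    p = idx.pvalues(k, n)
    r = idx.ranks(p, k)
    return [(t, float(p[i]), int(r[i])) for i, t in enumerate(idx.terms)]


# ---------------------------------------------------------------------------
# Background calibration


@dataclass
class RankBackground:
    """Per-term expected Fisher ranks under random input lists, stratified
    by input-list length bin.

    ``mean`` and ``sd`` are (n_bins, n_terms) arrays aligned with ``bins``
    (sorted list lengths) and ``terms``.
    """

    library_name: str
    terms: list[str]
    bins: list[int]
    mean: np.ndarray
    sd: np.ndarray
    n_simulations: int
    universe_size: int
    seed: int
    version: str = "1"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.n_simulations < 2:
            raise ValueError("n_simulations must be >= 2")
        if self.mean.shape != (len(self.bins), len(self.terms)):
            raise ValueError("mean shape does not match (bins, terms)")
        if self.sd.shape != self.mean.shape:
            raise ValueError("sd shape does not match mean shape")
        if np.any(self.sd < 0):
            raise ValueError("sd_rank must be non-negative")
        self._term_idx = {t: i for i, t in enumerate(self.terms)}

    def nearest_bin(self, length: int) -> int:
        """Index of the calibrated list-length bin nearest ``length``."""
        arr = np.asarray(self.bins)
        return int(np.argmin(np.abs(arr - length)))

    def term_stats(self, term: str, length: int) -> tuple[float, float]:
        """(mean_rank, sd_rank) for a term at the bin nearest ``length``."""
        b = self.nearest_bin(length)
        i = self._term_idx[term]
        return float(self.mean[b, i]), float(self.sd[b, i])

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "library_name": self.library_name,
            "seed": self.seed,
            "n_simulations": self.n_simulations,
            "universe_size": self.universe_size,
            "bins": list(map(int, self.bins)),
            "terms": list(self.terms),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RankBackground":
        return cls(
            library_name=d["library_name"],
            terms=list(d["terms"]),
            bins=list(d["bins"]),
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            n_simulations=int(d["n_simulations"]),
            universe_size=int(d["universe_size"]),
            seed=int(d["seed"]),
            version=str(d.get("version", "1")),
        )

    def save(self, sink: IO[str] | str) -> None:
        if isinstance(sink, str):
            with open(sink, "w", encoding="utf-8") as fh:
                self.save(fh)
            return
        json.dump(self.to_dict(), sink, indent=1)

    @classmethod
    def load(cls, source: IO[str] | str) -> "RankBackground":
        if isinstance(source, str):
            with open(source, "r", encoding="utf-8") as fh:
                return cls.load(fh)
        return cls.from_dict(json.load(source))


def calibrate_background(
    library: GeneSetLibrary,
    universe: Iterable[str] | None = None,
    n_lists: int = 1000,
    list_lengths: Sequence[int] = (300,),
    seed: int = 0,
) -> RankBackground:
    """Estimate each term's expected Fisher rank from random input lists.

    For every length in ``list_lengths``, ``n_lists`` gene lists are drawn
    uniformly without replacement from the universe, scored with the
    Fisher test, and ranked; the per-term mean and standard deviation of
    those ranks form the background. Fully reproducible from ``seed``.
    """
    if len(library) < 2:
        raise ValueError("background calibration needs >= 2 terms")
    if n_lists < 2:
        raise ValueError("n_lists must be >= 2")
    if not list_lengths:
        raise ValueError("list_lengths must be non-empty")
    idx = LibraryIndex(library, universe)
    uni_size = len(idx.universe)
    bins = sorted(set(int(L) for L in list_lengths))
    for L in bins:
        if not (1 <= L <= uni_size):
            raise ValueError(f"list length {L} outside [1, {uni_size}]")
    rng = np.random.default_rng(seed)
    means = np.empty((len(bins), idx.n_terms))
    sds = np.empty_like(means)
    for b, L in enumerate(bins):
        draws = np.empty((n_lists, L), dtype=np.int64)
        for j in range(n_lists):
            draws[j] = rng.choice(uni_size, size=L, replace=False)
        ranks = idx.rank_matrix(draws, L)
        means[b] = ranks.mean(axis=0)
        sds[b] = ranks.std(axis=0, ddof=1)
    return RankBackground(
        library_name=library.name,
        terms=idx.terms,
        bins=bins,
        mean=means,
        sd=sds,
        n_simulations=n_lists,
        universe_size=uni_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Enrichment tables


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-term result: overlap, Fisher p and rank, rank-deviation z,
    combined score. ``z_score``/``combined_score`` are None when no
    background was supplied or the term's rank variance is degenerate."""

    term: str
    overlap_genes: frozenset[str]
    term_size: int
    p_value: float
    fisher_rank: int
    z_score: float | None = None
    combined_score: float | None = None

    @property
    def k(self) -> int:
        return len(self.overlap_genes)


TSV_HEADER = ["Term", "Overlap (k/K)", "P-value", "Z-score", "Combined Score", "Genes"]


class EnrichmentTable:
    """Ordered enrichment records for one (input list, library) pair."""

    def __init__(
        self,
        records: Sequence[EnrichmentRecord],
        library_name: str = "",
        input_description: str = "",
        sort_mode: str = "p_value",
    ):
        if sort_mode not in SORT_MODES:
            raise ValueError(f"unknown sort_mode {sort_mode!r}")
        self.library_name = library_name
        self.input_description = input_description
        self.sort_mode = sort_mode
        self.records = self._sorted(list(records), sort_mode)

    @staticmethod
    def _sorted(
        records: list[EnrichmentRecord], mode: str
    ) -> list[EnrichmentRecord]:
        if mode == "p_value":
            key = lambda r: (r.p_value, -r.k, r.term)
        elif mode == "z_score":
            # None (un-scorable) terms sink to the bottom
            key = lambda r: (
                r.z_score is None,
                r.z_score if r.z_score is not None else 0.0,
                r.p_value,
                r.term,
            )
        else:  # combined, descending
            key = lambda r: (
                r.combined_score is None,
                -(r.combined_score if r.combined_score is not None else 0.0),
                r.p_value,
                r.term,
            )
        return sorted(records, key=key)

    def resort(self, sort_mode: str) -> "EnrichmentTable":
        """Return the same records sorted under another mode."""
        if sort_mode in ("z_score", "combined") and all(
            r.z_score is None for r in self.records
        ):
            raise ValueError(f"no z-scores available for sort_mode {sort_mode!r}")
        return EnrichmentTable(
            self.records, self.library_name, self.input_description, sort_mode
        )

    def top(self, n: int = 10) -> list[EnrichmentRecord]:
        return self.records[:n]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_tsv(self, sink: IO[str]) -> None:
        sink.write("\t".join(TSV_HEADER) + "\n")
        for r in self.records:
            z = "" if r.z_score is None else f"{r.z_score:.6g}"
            c = "" if r.combined_score is None else f"{r.combined_score:.6g}"
            sink.write(
                "\t".join(
                    [
                        r.term,
                        f"{r.k}/{r.term_size}",
                        f"{r.p_value:.6g}",
                        z,
                        c,
                        ";".join(sorted(r.overlap_genes)),
                    ]
                )
                + "\n"
            )

    def to_dict(self) -> dict:
        return {
            "library_name": self.library_name,
            "input_description": self.input_description,
            "sort_mode": self.sort_mode,
            "records": [
                {
                    "term": r.term,
                    "overlap_genes": sorted(r.overlap_genes),
                    "term_size": r.term_size,
                    "p_value": r.p_value,
                    "fisher_rank": r.fisher_rank,
                    "z_score": r.z_score,
                    "combined_score": r.combined_score,
                }
                for r in self.records
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnrichmentTable":
        records = [
            EnrichmentRecord(
                term=r["term"],
                overlap_genes=frozenset(r["overlap_genes"]),
                term_size=int(r["term_size"]),
                p_value=float(r["p_value"]),
                fisher_rank=int(r["fisher_rank"]),
                z_score=r.get("z_score"),
                combined_score=r.get("combined_score"),
            )
            for r in d["records"]
        ]
        return cls(
            records,
            library_name=d.get("library_name", ""),
            input_description=d.get("input_description", ""),
            sort_mode=d.get("sort_mode", "p_value"),
        )

    def to_json(self, sink: IO[str]) -> None:
        json.dump(self.to_dict(), sink, indent=1)

    @classmethod
    def from_json(cls, source: IO[str]) -> "EnrichmentTable":
        return cls.from_dict(json.load(source))


def enrich(
    input_list: InputGeneList,
    library: GeneSetLibrary,
    background: RankBackground | None = None,
    sort_mode: str = "p_value",
    universe: Iterable[str] | None = None,
) -> EnrichmentTable:
    """Run the full enrichment pipeline for one input list.

    ``sort_mode`` ∈ {"p_value", "z_score", "combined"}; the latter two
    require a ``background`` calibrated on the same library. Terms whose
    background rank variance is zero get no z/combined score and sort last
    under those modes (with a warning).
    """
    if sort_mode not in SORT_MODES:
        raise ValueError(f"unknown sort_mode {sort_mode!r}")
    if sort_mode in ("z_score", "combined") and background is None:
        raise ValueError(f"sort_mode {sort_mode!r} requires a calibrated background")
    idx = LibraryIndex(library, universe)
    if background is not None:
        missing = [t for t in idx.terms if t not in set(background.terms)]
        if missing:
            raise ValueError(
                f"background does not cover {len(missing)} library terms: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
    k, n = idx.overlaps(input_list)
    if n == 0:
        raise ValueError(
            "no input genes found in the universe; check that the gene "
            "list and the library/universe use the same symbol space"
        )
    p = idx.pvalues(k, n)
    ranks = idx.ranks(p, k)
    in_uni = input_list.genes & idx.universe
    records = []
    n_degenerate = 0
    for i, term in enumerate(idx.terms):
        overlap = frozenset(library[term].genes & in_uni)
        z = c = None
        if background is not None:
            mean_r, sd_r = background.term_stats(term, n)
            if sd_r > 0:
                z = rank_zscore(int(ranks[i]), (mean_r, sd_r))
                c = combined_score(float(p[i]), z)
            else:
                n_degenerate += 1
        records.append(
            EnrichmentRecord(
                term=term,
                overlap_genes=overlap,
                term_size=int(idx.K[i]),
                p_value=float(p[i]),
                fisher_rank=int(ranks[i]),
                z_score=z,
                combined_score=c,
            )
        )
    if n_degenerate:
        logger.warning(
            "%d terms have zero rank variance in the background and were "
            "excluded from z/combined scoring",
            n_degenerate,
        )
    return EnrichmentTable(
        records,
        library_name=library.name,
        input_description=input_list.description,
        sort_mode=sort_mode,
    )


# ---------------------------------------------------------------------------
# Benchmark harness


@dataclass
class BenchmarkResult:
    """Achieved rank of each labeled term under each scoring method."""

    ranks: dict[str, list[int]]  # method -> per-list achieved rank
    labels: list[str]

    def mean_rank(self, method: str) -> float:
        return float(np.mean(self.ranks[method]))

    def cumulative_histogram(self, method: str) -> tuple[list[int], list[int]]:
        """(sorted achieved ranks, cumulative counts) for plotting."""
        r = sorted(self.ranks[method])
        return r, list(range(1, len(r) + 1))


def benchmark_rank_recovery(
    library: GeneSetLibrary,
    perturbation_lists: Sequence[InputGeneList],
    background: RankBackground,
    universe: Iterable[str] | None = None,
) -> BenchmarkResult:
    """For each labeled input list, record the rank its label achieves
    under all three scoring methods.

    Each list must carry a ``label`` naming a library term. Summary
    statistics (mean rank per method, cumulative histograms) are exposed
    on the returned :class:`BenchmarkResult`.
    """
    for pl in perturbation_lists:
        if pl.label is None:
            raise ValueError("every benchmark list must carry a label")
        if pl.label not in library:
            raise ValueError(f"label {pl.label!r} is not a library term")
    ranks: dict[str, list[int]] = {m: [] for m in SORT_MODES}
    labels = []
    for pl in perturbation_lists:
        table = enrich(pl, library, background=background, universe=universe)
        for mode in SORT_MODES:
            ordered = table.resort(mode)
            pos = next(
                i for i, r in enumerate(ordered.records, 1) if r.term == pl.label
            )
            ranks[mode].append(pos)
        labels.append(pl.label)
    return BenchmarkResult(ranks=ranks, labels=labels)
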