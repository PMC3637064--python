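"""Gene-set data model and GMT serialization.

A gene-set library is an ordered collection of named gene sets ("terms").
Libraries are serialized in the GMT dialect: one set per line, tab-separated
``term<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "GmtParseError",
    "LibraryCategory",
    "GeneSet",
    "GeneSetLibrary",
    "LibraryStats",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "library_stats",
]


class GmtParseError(ValueError):
    """Raised on malformed GMT input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LibraryCategory(str, enum.Enum):
    """The six result-page categories a library may belong to."""

    TRANSCRIPTION = "transcription"
    PATHWAYS = "pathways"
    ONTOLOGIES = "ontologies"
    DISEASES_DRUGS = "diseases_drugs"
    CELL_TYPES = "cell_types"
    MISCELLANEOUS = "miscellaneous"


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace and uppercase.

    Normalization is idempotent. No alias/ID mapping is performed.

    Raises
    ------
    ValueError
        If the symbol is empty after stripping or contains internal
        whitespace.
    """
    s = symbol.strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise ValueError(f"gene symbol contains whitespace: {symbol!r}")
    return s


def _normalize_genes(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_symbol(g) for g in genes)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    ``genes`` are stored as a frozenset of normalized symbols; duplicates
    collapse under set semantics.
    """

    term: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("gene set term must be non-empty")
        object.__setattr__(self, "genes", _normalize_genes(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetLibrary:
    """An ordered collection of uniquely-named gene sets.

    The gene *universe* defaults to the union of all member sets; callers
    may override it (e.g. with a genome-wide symbol list) for consistency
    across libraries.
    """

    def __init__(
        self,
        sets: Iterable[GeneSet] = (),
        name: str = "",
        category: LibraryCategory = LibraryCategory.MISCELLANEOUS,
        universe: Iterable[str] | None = None,
    ):
        self.name = name
        self.category = LibraryCategory(category)
        self._sets: list[GeneSet] = []
        self._by_term: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)
        self._universe_override: frozenset[str] | None = (
            _normalize_genes(universe) if universe is not None else None
        )

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.term in self._by_term:
            raise ValueError(f"duplicate term in library: {gene_set.term!r}")
        if len(gene_set.genes) < 1:
            raise ValueError(f"term {gene_set.term!r} has an empty gene set")
        self._sets.append(gene_set)
        self._by_term[gene_set.term] = gene_set

    @property
    def sets(self) -> list[GeneSet]:
        return list(self._sets)

    @property
    def terms(self) -> list[str]:
        return [gs.term for gs in self._sets]

    @property
    def universe(self) -> frozenset[str]:
        if self._universe_override is not None:
            return self._universe_override
        out: set[str] = set()
        for gs in self._sets:
            out |= gs.genes
        return frozenset(out)

    def __getitem__(self, term: str) -> GeneSet:
        return self._by_term[term]

    def __contains__(self, term: str) -> bool:
        return term in self._by_term

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return [(s.term, s.genes) for s in self._sets] == [
            (s.term, s.genes) for s in other._sets
        ]

    def __repr__(self) -> str:
        return (
            f"GeneSetLibrary(name={self.name!r}, "
            f"category={self.category.value}, n_terms={len(self)})"
        )


@dataclass(frozen=True)
class LibraryStats:
    """Per-library summary: term count, distinct-gene coverage, mean set size."""

    n_terms: int
    gene_coverage: int
    mean_genes_per_term: float


def read_gmt(source: IO[str] | str, name: str = "", **kwargs) -> GeneSetLibrary:
    """Parse a GMT text stream (or path) into a :class:`GeneSetLibrary`.

    Each non-empty line must have at least 3 tab-separated fields:
    term, description, then one or more genes. Duplicate genes within a
    line collapse silently (set semantics, logged at debug level).

    Raises
    ------
    GmtParseError
        On a line with fewer than 3 fields, or a duplicate term label.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_gmt(fh, name=name or source, **kwargs)
    library = GeneSetLibrary(name=name, **kwargs)
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"expected >=3 tab-separated fields, got {len(fields)}", lineno
            )
        term, description = fields[0], fields[1]
        raw_genes = [g for g in fields[2:] if g.strip()]
        if not raw_genes:
            raise GmtParseError(f"term {term!r} has no genes", lineno)
        genes = _normalize_genes(raw_genes)
        if len(genes) < len(raw_genes):
            logger.debug(
                "line %d: %d duplicate genes collapsed in term %r",
                lineno,
                len(raw_genes) - len(genes),
                term,
            )
        try:
            library.add(GeneSet(term=term, description=description, genes=genes))
        except ValueError as exc:
            raise GmtParseError(str(exc), lineno) from exc
    return library


def write_gmt(library: GeneSetLibrary, sink: IO[str] | str) -> None:
    """Write a library as GMT. Genes are sorted lexicographically per line.

    An empty description is written as an empty field (the 3-field GMT
    minimum is always respected). Round-trips through :func:`read_gmt`.
    """
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            write_gmt(library, fh)
        return
    for gs in library:
        fields = [gs.term, gs.description, *sorted(gs.genes)]
        sink.write("\t".join(fields) + "\n")


def gmt_dumps(library: GeneSetLibrary) -> str:
    """Serialize a library to a GMT string."""
    buf = io.StringIO()
    write_gmt(library, buf)
    return buf.getvalue()


def library_stats(library: GeneSetLibrary) -> LibraryStats:
    """Compute (n_terms, distinct gene coverage, mean genes per term).

    An empty library yields ``LibraryStats(0, 0, 0.0)``.
    """
    n = len(library)
    if n == 0:
        return LibraryStats(0, 0, 0.0)
    total = sum(len(gs) for gs in library)
    coverage = len(frozenset().union(*(gs.genes for gs in library)))
    return LibraryStats(n, coverage, total / n)
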