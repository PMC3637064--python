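"""Toroidal grid layout of library terms and clustering significance.

All terms of a library are placed on a near-square grid whose edges wrap
around (a torus). Simulated annealing arranges the terms so that
neighboring cells hold similar terms (gene-content similarity, Jaccard by
default). A numerical permutation test then asks whether a given subset of
enriched terms sits closer together on the grid than random cell subsets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from enrichkit.genesets import GeneSetLibrary

__all__ = [
    "SimilarityMatrix",
    "AnnealingSchedule",
    "GridLayout",
    "ClusteringResult",
    "jaccard",
    "term_similarity",
    "grid_shape",
    "toroidal_distance",
    "layout_fitness",
    "anneal_layout",
    "cluster_significance",
    "export_grid",
]

EMPTY = -1  # padding-cell marker in assignment arrays


def jaccard(a: frozenset, b: frozenset) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both sets are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class SimilarityMatrix:
    """Symmetric term-by-term similarity in [0, 1] with unit diagonal."""

    terms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.terms)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape must be (n_terms, n_terms)")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        self.values = v
        self._idx = {t: i for i, t in enumerate(self.terms)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._idx[a], self._idx[b]])

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def term_similarity(
    library: GeneSetLibrary,
    method: Callable[[frozenset, frozenset], float] = jaccard,
) -> SimilarityMatrix:
    """Pairwise gene-content similarity between all library terms.

    ``method`` is any symmetric scorer of two gene sets into [0, 1]
    (defaults to the Jaccard index), so alternative co-occurrence measures
    can be plugged in.
    """
    if len(library) < 2:
        raise ValueError("similarity needs >= 2 terms")
    sets = [gs.genes for gs in library]
    for gs in library:
        if not gs.genes:
            raise ValueError(f"term {gs.term!r} has an empty gene set")
    n = len(sets)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = method(sets[i], sets[j])
    return SimilarityMatrix(terms=library.terms, values=v)


def grid_shape(n_terms: int) -> tuple[int, int]:
    """Smallest near-square (width, height), w >= h, w*h >= n, w - h <= 1."""
    if n_terms < 1:
        raise ValueError("need at least one term")
    h = int(math.isqrt(n_terms))
    if h * h >= n_terms:
        return h, h
    if h * (h + 1) >= n_terms:
        return h + 1, h
    return h + 1, h + 1


def toroidal_distance(
    cell_a: tuple[int, int],
    cell_b: tuple[int, int],
    width: int,
    height: int,
) -> float:
    """Euclidean distance on a torus: per axis, the shorter way around."""
    (ra, ca), (rb, cb) = cell_a, cell_b
    for r, c in ((ra, ca), (rb, cb)):
        if not (0 <= r < height and 0 <= c < width):
            raise ValueError(f"cell ({r}, {c}) outside {height}x{width} grid")
    dr = abs(ra - rb)
    dc = abs(ca - cb)
    dr = min(dr, height - dr)
    dc = min(dc, width - dc)
    return math.hypot(dr, dc)


@dataclass
class AnnealingSchedule:
    """Geometric cooling schedule for the layout annealer."""

    initial_temperature: float = 1.0
    cooling_factor: float = 0.95
    steps_per_temperature: int | None = None  # default: 100 * n_terms
    max_stale_stages: int = 3
    max_stages: int = 200

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.steps_per_temperature is not None and self.steps_per_temperature < 1:
            raise ValueError("steps_per_temperature must be >= 1")


def _assignment_grid(assignment: Mapping[tuple[int, int], str] | np.ndarray,
                     terms: Sequence[str], width: int, height: int) -> np.ndarray:
    """Convert a cell->term mapping into an int grid of term indices."""
    if isinstance(assignment, np.ndarray):
        return assignment
    idx = {t: i for i, t in enumerate(terms)}
    grid = np.full((height, width), EMPTY, dtype=np.int64)
    for (r, c), term in assignment.items():
        grid[r, c] = idx[term]
    return grid


def layout_fitness(
    assignment: Mapping[tuple[int, int], str] | np.ndarray,
    similarity: SimilarityMatrix,
    width: int,
    height: int,
) -> float:
    """Sum of similarities over all toroidally-adjacent 4-neighborhood
    pairs, each unordered pair counted once. Empty cells contribute 0."""
    grid = _assignment_grid(assignment, similarity.terms, width, height)
    placed = set(int(x) for x in grid.ravel() if x != EMPTY)
    if placed != set(range(similarity.n_terms)):
        raise ValueError("every term must be placed exactly once")
    sim = similarity.values
    total = 0.0
    # each cell owns one "right" and one "down" edge on the torus; on a
    # size-2 axis the two cells are joined by two distinct wrap edges,
    # each counted once (a 2x2 grid has 8 adjacencies)
    if width > 1:
        right = np.roll(grid, -1, axis=1)
        mask = (grid != EMPTY) & (right != EMPTY)
        total += sim[grid[mask], right[mask]].sum()
    if height > 1:
        down = np.roll(grid, -1, axis=0)
        mask = (grid != EMPTY) & (down != EMPTY)
        total += sim[grid[mask], down[mask]].sum()
    return float(total)


@dataclass
class GridLayout:
    """A toroidal placement of all terms, with its similarity matrix."""

    width: int
    height: int
    grid: np.ndarray  # (height, width) of term indices, EMPTY for padding
    similarity: SimilarityMatrix
    fitness: float
    seed: int
    schedule: AnnealingSchedule

    @property
    def assignment(self) -> dict[tuple[int, int], str]:
        """cell -> term mapping (padding cells omitted)."""
        out = {}
        for r in range(self.height):
            for c in range(self.width):
                t = int(self.grid[r, c])
                if t != EMPTY:
                    out[(r, c)] = self.similarity.terms[t]
        return out

    def cell_of(self, term: str) -> tuple[int, int]:
        t = self.similarity.terms.index(term)
        rs, cs = np.nonzero(self.grid == t)
        return int(rs[0]), int(cs[0])

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "fitness": self.fitness,
            "seed": self.seed,
            "terms": self.similarity.terms,
            "grid": self.grid.tolist(),
            "similarity": self.similarity.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridLayout":
        sim = SimilarityMatrix(terms=list(d["terms"]), values=np.asarray(d["similarity"]))
        return cls(
            width=int(d["width"]),
            height=int(d["height"]),
            grid=np.asarray(d["grid"], dtype=np.int64),
            similarity=sim,
            fitness=float(d["fitness"]),
            seed=int(d["seed"]),
            schedule=AnnealingSchedule(),
        )


def _neighbor_cells(r: int, c: int, width: int, height: int) -> list[tuple[int, int]]:
    out = []
    if height > 1:
        out.append(((r - 1) % height, c))
        if height > 2 or ((r + 1) % height, c) != ((r - 1) % height, c):
            out.append(((r + 1) % height, c))
    if width > 1:
        out.append((r, (c - 1) % width))
        if width > 2 or (r, (c + 1) % width) != (r, (c - 1) % width):
            out.append((r, (c + 1) % width))
    return out


def _incident_edges(
    cells: Sequence[tuple[int, int]], width: int, height: int
) -> set[tuple[int, int, str]]:
    """Edges touching any given cell, identified by (owner row, owner col,
    direction) in the same edge convention as :func:`layout_fitness`."""
    edges: set[tuple[int, int, str]] = set()
    for (r, c) in cells:
        if width > 1:
            edges.add((r, c, "R"))
            edges.add((r, (c - 1) % width, "R"))
        if height > 1:
            edges.add((r, c, "D"))
            edges.add(((r - 1) % height, c, "D"))
    return edges


def _local_energy(grid: np.ndarray, cells: Sequence[tuple[int, int]],
                  sim: np.ndarray, width: int, height: int) -> float:
    """Sum of adjacency similarities over the edges incident to the given
    cells (consistent with the global edge counting)."""
    total = 0.0
    for (r, c, d) in _incident_edges(cells, width, height):
        a = grid[r, c]
        if d == "R":
            b = grid[r, (c + 1) % width]
        else:
            b = grid[(r + 1) % height, c]
        if a != EMPTY and b != EMPTY:
            total += sim[a, b]
    return total


def anneal_layout(
    similarity: SimilarityMatrix,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
) -> GridLayout:
    """Arrange terms on the torus by simulated annealing.

    Starts from a random placement, proposes random cell-pair swaps, and
    accepts with Metropolis probability ``min(1, exp(Δfitness / T))``
    under geometric cooling. The best-so-far arrangement is returned, so
    the result's fitness never falls below the initial placement's.
    Deterministic for a given seed.
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    n = similarity.n_terms
    if n < 2:
        raise ValueError("annealing needs >= 2 terms")
    width, height = grid_shape(n)
    n_cells = width * height
    rng = np.random.default_rng(seed)
    flat = np.full(n_cells, EMPTY, dtype=np.int64)
    flat[:n] = np.arange(n)
    rng.shuffle(flat)
    grid = flat.reshape(height, width)
    sim = similarity.values
    fitness = layout_fitness(grid, similarity, width, height)
    best_grid, best_fitness = grid.copy(), fitness
    steps = schedule.steps_per_temperature or 100 * n
    T = schedule.initial_temperature
    stale = 0
    for _stage in range(schedule.max_stages):
        accepted = 0
        cells_a = rng.integers(0, n_cells, size=steps)
        cells_b = rng.integers(0, n_cells, size=steps)
        unif = rng.random(size=steps)
        for s in range(steps):
            i, j = int(cells_a[s]), int(cells_b[s])
            if i == j:
                continue
            ra, ca = divmod(i, width)
            rb, cb = divmod(j, width)
            if grid[ra, ca] == EMPTY and grid[rb, cb] == EMPTY:
                continue
            cells = [(ra, ca), (rb, cb)]
            before = _local_energy(grid, cells, sim, width, height)
            grid[ra, ca], grid[rb, cb] = grid[rb, cb], grid[ra, ca]
            after = _local_energy(grid, cells, sim, width, height)
            delta = after - before
            if delta >= 0 or unif[s] < math.exp(delta / T):
                # zero-delta shuffles don't count as progress for the
                # staleness stop rule
                if abs(delta) > 1e-15:
                    accepted += 1
                fitness += delta
                if fitness > best_fitness + 1e-12:
                    best_fitness = fitness
                    best_grid = grid.copy()
            else:
                grid[ra, ca], grid[rb, cb] = grid[rb, cb], grid[ra, ca]
        stale = stale + 1 if accepted == 0 else 0
        if stale >= schedule.max_stale_stages:
            break
        T *= schedule.cooling_factor
    # guard against float drift in the incremental bookkeeping
    best_fitness = layout_fitness(best_grid, similarity, width, height)
    return GridLayout(
        width=width,
        height=height,
        grid=best_grid,
        similarity=similarity,
        fitness=best_fitness,
        seed=seed,
        schedule=schedule,
    )


@dataclass
class ClusteringResult:
    """Permutation test of spatial clustering of enriched cells.

    ``statistic`` is the mean pairwise toroidal distance among the
    enriched cells (smaller = more clustered); the null redraws the same
    number of occupied cells uniformly without replacement.
    """

    statistic: float
    z: float
    p: float
    n_null: int
    seed: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")
        if self.n_null < 100:
            raise ValueError("n_null must be >= 100")
        self.significant = self.p < 0.1

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "z": self.z,
            "p": self.p,
            "n_null": self.n_null,
            "seed": self.seed,
            "significant": self.significant,
        }


def _mean_pairwise(dist: np.ndarray, idx: np.ndarray) -> float:
    sub = dist[np.ix_(idx, idx)]
    m = len(idx)
    return float(sub[np.triu_indices(m, k=1)].mean())


def cluster_significance(
    layout: GridLayout,
    enriched_terms: Iterable[str],
    n_null: int = 1000,
    seed: int = 0,
) -> ClusteringResult:
    """Test whether enriched terms cluster on the grid.

    One-sided empirical p (small statistic = clustered) with add-one
    smoothing: ``p = (1 + #{null <= observed}) / (n_null + 1)``.
    """
    enriched = list(dict.fromkeys(enriched_terms))
    if len(enriched) < 2:
        raise ValueError("need >= 2 enriched terms")
    occupied = [
        (r, c)
        for r in range(layout.height)
        for c in range(layout.width)
        if layout.grid[r, c] != EMPTY
    ]
    cell_index = {cell: i for i, cell in enumerate(occupied)}
    term_cell = {v: k for k, v in layout.assignment.items()}
    try:
        obs_idx = np.array([cell_index[term_cell[t]] for t in enriched])
    except KeyError as exc:
        raise ValueError(f"enriched term not placed on the grid: {exc}") from exc
    n_occ = len(occupied)
    rows = np.array([c[0] for c in occupied], dtype=np.float64)
    cols = np.array([c[1] for c in occupied], dtype=np.float64)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    dr = np.minimum(dr, layout.height - dr)
    dc = np.minimum(dc, layout.width - dc)
    dist = np.hypot(dr, dc)
    observed = _mean_pairwise(dist, obs_idx)
    rng = np.random.default_rng(seed)
    m = len(enriched)
    null = np.empty(n_null)
    for t in range(n_null):
        draw = rng.choice(n_occ, size=m, replace=False)
        null[t] = _mean_pairwise(dist, draw)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    # tolerance shields ties from float summation-order noise
    tol = 1e-9 * max(1.0, abs(observed))
    z = (observed - null_mean) / null_sd if null_sd > tol else 0.0
    p = (1.0 + float(np.sum(null <= observed + tol))) / (n_null + 1.0)
    return ClusteringResult(statistic=observed, z=z, p=min(p, 1.0), n_null=n_null, seed=seed)


GRID_VIEW_MODES = ("p_value_view", "grid_view")


def export_grid(
    layout: GridLayout,
    table,
    mode: str = "p_value_view",
    enriched_terms: Iterable[str] | None = None,
    clustering: ClusteringResult | None = None,
    top_n: int = 10,
) -> dict:
    """Serialize a layout plus enrichment results as a JSON-able payload.

    ``p_value_view``: enriched cells get brightness = −log10(p) scaled to
    [0, 1] over the enriched terms; everything else is dark.
    ``grid_view``: every cell's brightness is its mean similarity to its
    toroidal neighbors; enriched cells are flagged ``circled``.
    """
    if mode not in GRID_VIEW_MODES:
        raise ValueError(f"unknown grid view mode {mode!r}")
    if enriched_terms is None:
        enriched = [r.term for r in table.top(top_n)]
    else:
        enriched = list(enriched_terms)
    enriched_set = set(enriched)
    pvals = {r.term: r.p_value for r in table}
    logs = {
        t: -math.log10(max(pvals[t], 1e-300)) for t in enriched if t in pvals
    }
    max_log = max(logs.values()) if logs else 1.0
    sim = layout.similarity.values
    cells = []
    for r in range(layout.height):
        for c in range(layout.width):
            t = int(layout.grid[r, c])
            if t == EMPTY:
                cells.append({"row": r, "col": c, "term": None, "brightness": 0.0})
                continue
            term = layout.similarity.terms[t]
            if mode == "p_value_view":
                b = logs.get(term, 0.0) / max_log if max_log > 0 else 0.0
                cell = {"row": r, "col": c, "term": term, "brightness": min(b, 1.0)}
            else:
                nbrs = [
                    int(layout.grid[nr, nc])
                    for nr, nc in _neighbor_cells(r, c, layout.width, layout.height)
                ]
                vals = [sim[t, nb] for nb in nbrs if nb != EMPTY]
                b = float(np.mean(vals)) if vals else 0.0
                cell = {
                    "row": r,
                    "col": c,
                    "term": term,
                    "brightness": min(b, 1.0),
                    "circled": term in enriched_set,
                }
            cells.append(cell)
    payload = {
        "mode": mode,
        "width": layout.width,
        "height": layout.height,
        "fitness": layout.fitness,
        "seed": layout.seed,
        "cells": cells,
        "clustering": clustering.to_dict() if clustering is not None else None,
    }
    return payload
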