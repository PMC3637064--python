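"""Sparse nearest-neighbor networks of top enriched terms.

Each of the top enriched terms (ten by default) is linked to the single
other top term with the highest gene-content similarity; duplicate
unordered edges are merged, which keeps the network sparse and readable.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import IO, Mapping

import networkx as nx

from enrichkit.enrich import EnrichmentTable
from enrichkit.gridviz import SimilarityMatrix

__all__ = ["TermNetwork", "build_term_network", "export_network", "parse_network"]

EXPORT_FORMATS = ("json", "graphml", "edge_tsv")


@dataclass(frozen=True)
class TermNode:
    term: str
    p_value: float
    z_score: float | None
    combined_score: float | None


@dataclass
class TermNetwork:
    """Undirected nearest-neighbor graph over the top enriched terms."""

    nodes: list[TermNode]
    edges: list[tuple[str, str, float]]  # (term_a, term_b, similarity), a < b

    def __post_init__(self) -> None:
        names = [n.term for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node terms")
        seen = set()
        for a, b, _w in self.edges:
            if a == b:
                raise ValueError("self-loops are not allowed")
            key = frozenset({a, b})
            if key in seen:
                raise ValueError(f"duplicate edge {a}--{b}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "term": n.term,
                    "p_value": n.p_value,
                    "z_score": n.z_score,
                    "combined_score": n.combined_score,
                }
                for n in self.nodes
            ],
            "edges": [
                {"source": a, "target": b, "weight": w} for a, b, w in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TermNetwork":
        nodes = [
            TermNode(
                term=n["term"],
                p_value=float(n["p_value"]),
                z_score=n.get("z_score"),
                combined_score=n.get("combined_score"),
            )
            for n in d["nodes"]
        ]
        edges = [
            (e["source"], e["target"], float(e["weight"])) for e in d["edges"]
        ]
        return cls(nodes=nodes, edges=edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.term,
                p_value=n.p_value,
                z_score=n.z_score if n.z_score is not None else float("nan"),
                combined_score=(
                    n.combined_score if n.combined_score is not None else float("nan")
                ),
            )
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def build_term_network(
    table: EnrichmentTable,
    similarity: SimilarityMatrix,
    top_n: int = 10,
) -> TermNetwork:
    """Connect each of the top ``top_n`` enriched terms to its single most
    similar other top term.

    Nearest-neighbor ties are broken by better table rank, then
    lexicographic term label. Duplicate unordered edges merge, so the edge
    count lies in [ceil(n/2), n] for n >= 2 nodes.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(table) == 0:
        raise ValueError("enrichment table is empty")
    top = table.top(top_n)
    covered = set(similarity.terms)
    for r in top:
        if r.term not in covered:
            raise ValueError(f"similarity matrix does not cover term {r.term!r}")
    nodes = [
        TermNode(
            term=r.term,
            p_value=r.p_value,
            z_score=r.z_score,
            combined_score=r.combined_score,
        )
        for r in top
    ]
    rank_of = {r.term: i for i, r in enumerate(top)}
    edge_set: dict[frozenset, float] = {}
    if len(top) >= 2:
        for r in top:
            candidates = [o.term for o in top if o.term != r.term]
            # highest similarity; ties: better (smaller) table rank, then label
            best = min(
                candidates,
                key=lambda t: (-similarity[r.term, t], rank_of[t], t),
            )
            edge_set[frozenset({r.term, best})] = similarity[r.term, best]
    edges = sorted(
        (tuple(sorted(pair)) + (w,)) for pair, w in edge_set.items()
    )
    return TermNetwork(nodes=nodes, edges=[(a, b, w) for a, b, w in edges])


def export_network(network: TermNetwork, format: str = "json") -> str:
    """Serialize a term network as JSON, GraphML, or a TSV edge list."""
    if format == "json":
        return json.dumps(network.to_dict(), indent=1)
    if format == "graphml":
        buf = io.BytesIO()
        nx.write_graphml(network.to_networkx(), buf)
        return buf.getvalue().decode("utf-8")
    if format == "edge_tsv":
        lines = ["term_a\tterm_b\tweight"]
        for a, b, w in network.edges:
            lines.append(f"{a}\t{b}\t{w:.6g}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown network export format {format!r}")


def parse_network(serialized: str, format: str = "json") -> TermNetwork:
    """Inverse of :func:`export_network` for the json format; graphml is
    parsed via networkx (node attributes preserved)."""
    if format == "json":
        return TermNetwork.from_dict(json.loads(serialized))
    if format == "graphml":
        g = nx.read_graphml(io.BytesIO(serialized.encode("utf-8")))
        nodes = [
            TermNode(
                term=t,
                p_value=float(d.get("p_value", 1.0)),
                z_score=d.get("z_score"),
                combined_score=d.get("combined_score"),
            )
            for t, d in g.nodes(data=True)
        ]
        edges = [
            (min(a, b), max(a, b), float(d.get("weight", 0.0)))
            for a, b, d in g.edges(data=True)
        ]
        return TermNetwork(nodes=nodes, edges=sorted(edges))
    raise ValueError(f"unknown network parse format {format!r}")
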