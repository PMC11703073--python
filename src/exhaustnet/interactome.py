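"""Directed interactome assembly, outdegree edge weighting, dummy augmentation.

The network is a directed graph of regulatory interactions (TF-target,
kinase-substrate, phosphatase-substrate, ligand-receptor, other). Each edge
e = (x, y) is weighted by the reciprocal outdegree of its source,
w(e) = 1/k_out(x), and carries cost c(e) = 1 - w(e): edges leaving promiscuous
hubs are expensive, so the forest optimization prefers specific regulators.

Before solving, an artificial dummy root is attached to a candidate root set
(all nodes, or just the prized ones) with cost-omega edges; each dummy edge
used by a solution opens one tree, so the total dummy cost equals the
objective's omega*kappa tree-count term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "Interaction",
    "Interactome",
    "AugmentedGraph",
    "DUMMY",
    "INTERACTION_KINDS",
    "assemble",
    "compute_costs",
    "attach_dummy",
]

DUMMY = "__DUMMY__"

INTERACTION_KINDS = (
    "tf-target",
    "kinase-substrate",
    "phosphatase-substrate",
    "ligand-receptor",
    "other",
)


@dataclass(frozen=True)
class Interaction:
    """One directed interaction: source (tail) acts on target (head)."""

    source: str
    target: str
    kind: str = "other"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target must be non-empty node ids")
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(
                f"kind must be one of {INTERACTION_KINDS}, got {self.kind!r}"
            )


@dataclass
class Interactome:
    """Directed graph with per-edge weight w and cost c = 1 - w.

    The underlying container is a :class:`networkx.DiGraph`; edge attributes
    are ``kind``, ``provenance`` and, after :func:`compute_costs`, ``w`` and
    ``c``. Node identifiers are case-sensitive gene symbols.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def k_out(self, node: str) -> int:
        return self.graph.out_degree(node) if node in self.graph else 0

    def degree(self, node: str) -> int:
        return self.graph.degree(node) if node in self.graph else 0

    def cost(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["c"])

    def interactions(self) -> list[Interaction]:
        return [
            Interaction(u, v, d.get("kind", "other"), d.get("provenance", ""))
            for u, v, d in self.graph.edges(data=True)
        ]


@dataclass(frozen=True)
class AugmentedGraph:
    """Interactome plus the dummy root and its cost-omega edges."""

    base: Interactome
    root_candidates: frozenset[str]
    omega: float
    dummy: str = DUMMY

    def __post_init__(self) -> None:
        if self.dummy in self.base.nodes:
            raise ValueError(f"dummy id {self.dummy!r} collides with a real node")
        if not self.root_candidates <= self.base.nodes:
            extra = self.root_candidates - self.base.nodes
            raise ValueError(f"root candidates not in graph: {sorted(extra)}")


def assemble(interactions: Iterable[Interaction]) -> Interactome:
    """Build the interactome: drop self-loops, collapse duplicate (source, target).

    When parallel annotations are collapsed their kinds are concatenated into
    the surviving edge's provenance, e.g. "tf-target;kinase-substrate".
    """
    g = nx.DiGraph()
    for it in interactions:
        if it.source == it.target:
            g.add_node(it.source)  # self-loops can never join a forest
            continue
        if g.has_edge(it.source, it.target):
            d = g.edges[it.source, it.target]
            kinds = d["provenance"].split(";") if d["provenance"] else [d["kind"]]
            if it.kind not in kinds:
                kinds.append(it.kind)
            d["provenance"] = ";".join(kinds)
        else:
            g.add_edge(it.source, it.target, kind=it.kind, provenance=it.kind)
    return Interactome(graph=g)


def compute_costs(g: Interactome) -> Interactome:
    """Assign w(e) = 1/k_out(source) and c(e) = 1 - w(e) to every edge.

    Outdegrees are taken on the deduplicated, self-loop-free graph, so the
    out-edge weights of every node sum to exactly 1.
    """
    out = Interactome(graph=g.graph.copy())
    for node in out.graph.nodes:
        k = out.graph.out_degree(node)
        if k == 0:
            continue
        w = 1.0 / k
        for _, _, d in out.graph.out_edges(node, data=True):
            d["w"] = w
            d["c"] = 1.0 - w
    return out


def attach_dummy(
    g: Interactome,
    policy: str = "prized",
    omega: float = 1.0,
    prizes: "object | None" = None,
) -> AugmentedGraph:
    """Attach the dummy root to a candidate root set with cost-omega edges.

    policy="all" roots every node; policy="prized" (default) roots only nodes
    with a positive prize, mirroring the convention of rooting trees at
    terminals. The base graph is left untouched; the dummy lives only in the
    :class:`AugmentedGraph` wrapper and is stripped from solutions.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if policy == "all":
        roots = frozenset(g.nodes)
    elif policy == "prized":
        if prizes is None:
            raise ValueError("policy='prized' requires a prize map")
        prize_map = getattr(prizes, "prizes", prizes)
        roots = frozenset(n for n in g.nodes if prize_map.get(n, 0.0) > 0)
    else:
        raise ValueError(f"unknown root policy {policy!r} (use 'all' or 'prized')")
    return AugmentedGraph(base=g, root_candidates=roots, omega=float(omega))
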