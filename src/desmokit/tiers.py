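"""Hierarchical tier classification of an interactome around a bait root.

An interactome identified by proximity labeling is organized into layers by
how far each hit sits from the bait in a curated protein-protein interaction
graph: primary interactors bind the bait directly, secondary interactors
bind primary interactors but not the bait, and so on.  With undirected
edges this membership rule is exactly unit-weight shortest-path layering,
which is what :func:`assign_tiers` computes (breadth-first search from the
root).  A gene linked both to the root and to a tier-1 gene is primary:
the shortest distance wins.

Genes that cannot be placed within ``max_tier`` hops go to ``unconnected``
with a reason code distinguishing genes with no edges at all (``isolated``),
genes with edges but no path to the root (``unreachable``), and genes whose
shortest path exceeds the tier cap (``beyond_max_tier``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io_core import EdgeList

__all__ = ["TierAssignment", "TierStats", "assign_tiers",
           "tier_shared_fraction", "direct_binders"]

TIER_NAMES = ("primary", "secondary", "tertiary", "quaternary")


@dataclass
class TierAssignment:
    """Root-anchored layering of an interactome: tiers + unconnected set."""

    root: str
    tiers: list[set[str]]
    unconnected: set[str]
    reasons: dict[str, str] = field(default_factory=dict)

    def tier_of(self, gene: str) -> int | None:
        """1-based tier index of a gene, or None if unconnected/root."""
        for k, tier in enumerate(self.tiers, start=1):
            if gene in tier:
                return k
        return None

    def all_genes(self) -> set[str]:
        out = set().union(*self.tiers) if self.tiers else set()
        return out | self.unconnected

    def validate_partition(self, interactome: set[str]) -> None:
        """Assert tiers + unconnected partition the non-root interactome."""
        parts = [*self.tiers, self.unconnected]
        total = sum(len(p) for p in parts)
        union = set().union(*parts)
        if len(union) != total:
            raise AssertionError("tier sets are not pairwise disjoint")
        if union != interactome - {self.root}:
            raise AssertionError("tiers + unconnected != interactome \\ {root}")


@dataclass
class TierStats:
    """Per-tier sizes and shared-with-reference percentages."""

    sizes: list[int]
    shared_pct: list[float | None]  # None for empty tiers

    def shared_pct_display(self) -> list[int | None]:
        return [None if p is None else int(round(p)) for p in self.shared_pct]


def assign_tiers(interactome: Iterable[str], edges: EdgeList, root: str,
                 max_tier: int = 4) -> TierAssignment:
    """Layer an interactome by shortest-path distance from the root bait.

    Tier k (k = 1..max_tier) holds genes at unit-weight shortest-path
    distance k from ``root``; everything farther, unreachable or edgeless
    goes to ``unconnected``.  Deterministic: the result depends only on the
    edge set.
    """
    interactome = set(interactome)
    if not interactome:
        raise ValueError("interactome is empty")
    if root not in interactome and root not in edges.nodes():
        raise ValueError(f"root {root!r} missing from interactome and edges")
    nodes = interactome | {root}
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for a, b in edges.edges:
        if a in nodes and b in nodes:
            graph.add_edge(a, b)
    dist = nx.single_source_shortest_path_length(graph, root)
    tiers: list[set[str]] = [set() for _ in range(max_tier)]
    unconnected: set[str] = set()
    reasons: dict[str, str] = {}
    for gene in nodes - {root}:
        d = dist.get(gene)
        if d is not None and 1 <= d <= max_tier:
            tiers[d - 1].add(gene)
        else:
            unconnected.add(gene)
            if graph.degree(gene) == 0:
                reasons[gene] = "isolated"
            elif d is None:
                reasons[gene] = "unreachable"
            else:
                reasons[gene] = "beyond_max_tier"
    assignment = TierAssignment(root=root, tiers=tiers, unconnected=unconnected,
                                reasons=reasons)
    assignment.validate_partition(nodes)
    return assignment


def tier_shared_fraction(assignment: TierAssignment,
                         reference: Iterable[str]) -> TierStats:
    """Percentage of each tier shared with a reference gene set.

    Exact percentages are retained; :meth:`TierStats.shared_pct_display`
    rounds to the nearest integer for display.  Empty tiers report None.
    """
    ref = set(reference)
    sizes: list[int] = []
    pct: list[float | None] = []
    for tier in assignment.tiers:
        sizes.append(len(tier))
        if not tier:
            pct.append(None)
        else:
            pct.append(100.0 * len(tier & ref) / len(tier))
    return TierStats(sizes=sizes, shared_pct=pct)


def direct_binders(core: Iterable[str], edges: EdgeList,
                   interactome: Iterable[str]
                   ) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Peripheral interactome genes adjacent to each core-complex protein.

    Returns ``(per_core_neighbors, union, multi_binders)`` where core-core
    edges are excluded and ``multi_binders`` lists peripheral genes adjacent
    to more than one core protein.
    """
    core = set(core)
    pool = set(interactome) - core
    neighbors: dict[str, set[str]] = {c: set() for c in core}
    for a, b in edges.edges:
        if a in core and b in pool:
            neighbors[a].add(b)
        if b in core and a in pool:
            neighbors[b].add(a)
    union = set().union(*neighbors.values()) if neighbors else set()
    counts: dict[str, int] = {}
    for binders in neighbors.values():
        for g in binders:
            counts[g] = counts.get(g, 0) + 1
    multi = {g for g, c in counts.items() if c > 1}
    return neighbors, union, multi
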