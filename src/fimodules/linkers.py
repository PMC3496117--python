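"""Linker gene inference: connect the seed genes into one subnetwork.

A minimum-spanning-tree heuristic for the node-weighted Steiner problem:
build the complete graph on the seeds weighted by hop distance, take its
MST, and expand every tree edge into a concrete shortest path in the
network.  Non-seed genes on those paths are the *linkers* (the green
diamonds of the exported diagrams).  Because the plain MST expansion can
overshoot the minimum number of linkers, the initial solution is
refined: among equal-length shortest paths the expansion prefers nodes
already selected, redundant linkers are pruned, and a small
node-insertion local search (single nodes and adjacent pairs) swaps in
hub genes that let several path linkers be pruned at once.  On small
instances this reaches the exhaustive Steiner-node optimum.

The final subnetwork keeps all network edges among the selected nodes,
not only the tree paths, so densely interconnected clusters stay
visibly dense.  Everything is deterministic: MST ties are broken by
sorted endpoint names, equal-cost paths by the lexicographically
smallest node sequence, and local-search moves run in sorted order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx

from .network import FINetwork, normalize_symbol

__all__ = ["LinkerSubnetwork", "infer_linkers"]

_LOG = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkerSubnetwork:
    """Seeds plus inferred linkers with the induced connecting edges."""

    seeds: frozenset[str]
    linkers: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.seeds & self.linkers:
            raise ValueError("linkers must be disjoint from seeds")

    @property
    def nodes(self) -> frozenset[str]:
        return self.seeds | self.linkers

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def roles(self) -> dict[str, str]:
        roles = {s: "seed" for s in self.seeds}
        roles.update({l: "linker" for l in self.linkers})
        return roles


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _reuse_shortest_path(
    g: nx.Graph, src: str, dst: str, included: frozenset[str]
) -> list[str]:
    """Among shortest src→dst paths, minimize the count of nodes outside
    ``included``; remaining ties go to the lexicographically smallest
    node sequence.  Dynamic program over BFS distance-to-target layers.
    """
    dist = nx.single_source_shortest_path_length(g, dst)
    if src not in dist:
        raise nx.NetworkXNoPath(f"{src} and {dst} are disconnected")

    @lru_cache(maxsize=None)
    def best(u: str) -> tuple[int, tuple[str, ...]]:
        if u == dst:
            return (0, (u,))
        options = []
        for w in g[u]:
            if dist.get(w, -1) == dist[u] - 1:
                cost, tail = best(w)
                options.append((cost + (0 if w in included else 1), tail))
        cost, tail = min(options)
        return (cost, (u,) + tail)

    path = list(best(src)[1])
    best.cache_clear()
    return path


def _spans_seeds(g: nx.Graph, nodes: set[str], seeds: list[str]) -> bool:
    h = g.subgraph(nodes)
    first = seeds[0]
    return all(nx.has_path(h, first, s) for s in seeds[1:])


def _prune(g: nx.Graph, included: set[str], seeds: list[str]) -> set[str]:
    """Drop every linker whose removal keeps the seeds connected, in
    deterministic sorted order, to a fixed point."""
    seed_set = set(seeds)
    changed = True
    while changed:
        changed = False
        for l in sorted(included - seed_set):
            if _spans_seeds(g, included - {l}, seeds):
                included = included - {l}
                changed = True
    return included


def infer_linkers(
    net: FINetwork, seeds: Sequence[str] | frozenset[str]
) -> LinkerSubnetwork:
    """Connect all seeds into one subnetwork with a minimal set of linkers.

    Steps: (i) hop distances between all seed pairs; (ii) Kruskal MST of
    the complete seed graph (ties by sorted endpoints); (iii) each MST
    edge expanded into a shortest path preferring already-selected
    nodes; (iv) redundant linkers pruned and a node-insertion local
    search applied; (v) linkers = surviving non-seed nodes; edges =
    every network edge internal to seeds ∪ linkers.

    Raises if some seed pair is unreachable (restrict to the largest
    component first), listing the components involved.
    """
    seed_list = sorted({normalize_symbol(s) for s in seeds})
    if len(seed_list) == 0:
        raise ValueError("empty seed set")
    for s in seed_list:
        if s not in net.graph:
            raise KeyError(f"seed gene {s!r} not in network")
    g = net.graph
    if len(seed_list) == 1:
        only = frozenset(seed_list)
        return LinkerSubnetwork(seeds=only, linkers=frozenset(), edges=frozenset())

    # reachability check with component listing
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = i
    seed_comps: dict[int, list[str]] = {}
    for s in seed_list:
        seed_comps.setdefault(comp_of[s], []).append(s)
    if len(seed_comps) > 1:
        parts = "; ".join(
            f"component {c}: {sorted(m)[:5]}" for c, m in sorted(seed_comps.items())
        )
        raise ValueError(f"seeds span {len(seed_comps)} components — {parts}")

    # hop distances among seeds
    hop: dict[tuple[str, str], int] = {}
    for s in seed_list:
        lengths = nx.single_source_shortest_path_length(g, s)
        for t in seed_list:
            if s < t:
                hop[(s, t)] = lengths[t]

    # Kruskal on the complete seed graph, deterministic tie order
    uf = _UnionFind(seed_list)
    mst_edges: list[tuple[str, str]] = []
    for (a, b), w in sorted(hop.items(), key=lambda kv: (kv[1], kv[0])):
        if uf.union(a, b):
            mst_edges.append((a, b))

    # expand tree edges, preferring nodes already selected
    included: set[str] = set(seed_list)
    for a, b in sorted(mst_edges):
        included.update(_reuse_shortest_path(g, a, b, frozenset(included)))

    included = _prune(g, included, seed_list)
    included = _insertion_search(g, included, seed_list)

    seeds_f = frozenset(seed_list)
    linkers = frozenset(included - seeds_f)
    internal = frozenset(
        tuple(sorted((u, v))) for u, v in g.subgraph(included).edges
    )
    _LOG.info(
        "linker subnetwork: %d seeds + %d linkers, %d edges",
        len(seeds_f),
        len(linkers),
        len(internal),
    )
    return LinkerSubnetwork(seeds=seeds_f, linkers=linkers, edges=internal)


def _insertion_search(
    g: nx.Graph, included: set[str], seeds: list[str]
) -> set[str]:
    """Local search: insert one node, or an adjacent pair, adjacent to the
    current solution and re-prune; accept whenever the linker count
    drops.  First-improvement with sorted candidate order keeps the
    search deterministic.
    """
    seed_set = set(seeds)
    improved = True
    while improved:
        improved = False
        base = len(included - seed_set)
        if base < 2:  # a single insertion must allow pruning >= 2 linkers
            break
        frontier = sorted(
            {w for n in included for w in g[n] if w not in included}
        )
        for h in frontier:
            trial = _prune(g, included | {h}, seeds)
            if len(trial - seed_set) < base:
                included = trial
                improved = True
                break
        if improved:
            continue
        for h1 in frontier:
            for h2 in sorted(w for w in g[h1] if w not in included and w != h1):
                trial = _prune(g, included | {h1, h2}, seeds)
                if len(trial - seed_set) < base:
                    included = trial
                    improved = True
                    break
            if improved:
                break
    return included
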