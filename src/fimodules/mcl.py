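"""Markov Cluster Algorithm (MCL) and the cluster-size filters.

MCL simulates random-walk flow on a graph.  The column-stochastic
transition matrix is alternately *expanded* (raised to a matrix power,
letting flow spread) and *inflated* (raised to an entrywise power and
column-renormalized, sharpening strong flow and starving weak flow)
until the process converges; the surviving flow pattern decomposes the
graph into clusters.  Inflation controls granularity: 1.6 — the default
here — gives the coarse, pathway-sized clusters this pipeline is after;
larger values fragment the graph further.

The implementation is dense (numpy), adequate for the linker-augmented
subnetworks of up to a few thousand nodes this package clusters.
Stabilization choices: unit self-loops before normalization, entry
pruning below 1e-5 with per-column renormalization, and deterministic
resolution of the (rare) nodes attracted to several attractor systems.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .linkers import LinkerSubnetwork

__all__ = ["MCLParams", "ClusterSet", "mcl_cluster", "filter_clusters", "mcl_matrix"]

_LOG = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 1.6
    expansion: int = 2
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iter: int = 200
    self_loop_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ClusterSet:
    """Disjoint, exhaustive partition of the subnetwork nodes.

    ``clusters`` are sorted by decreasing size then smallest member.
    ``retained`` holds the clusters passing the size filter (set by
    :func:`filter_clusters`); ``flagged`` the ones large enough to
    report individually.  ``converged`` is False when the flow matrix
    did not settle within ``max_iter`` (the current interpretation is
    still returned, flagged in any output).
    """

    clusters: list[frozenset[str]]
    params: MCLParams
    converged: bool = True
    retained: list[frozenset[str]] = field(default_factory=list)
    flagged: list[frozenset[str]] = field(default_factory=list)
    min_fraction: float | None = None
    report_min_size: int | None = None

    @property
    def n_nodes(self) -> int:
        return sum(len(c) for c in self.clusters)

    def labels(self) -> dict[str, int]:
        """Node → cluster index (by the sorted cluster order)."""
        return {n: i for i, c in enumerate(self.clusters) for n in c}

    def write(self, path: str | Path) -> None:
        retained = set(map(frozenset, self.retained))
        flagged = set(map(frozenset, self.flagged))
        rows = []
        for i, c in enumerate(self.clusters):
            rows.append(
                {
                    "cluster_id": i,
                    "size": len(c),
                    "retained_flag": int(c in retained),
                    "report_flag": int(c in flagged),
                    "converged": int(self.converged),
                    "members": ",".join(sorted(c)),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _as_graph(sub: LinkerSubnetwork | nx.Graph) -> nx.Graph:
    if isinstance(sub, LinkerSubnetwork):
        return sub.graph
    return sub


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    # a column emptied by pruning falls back to a pure self-loop
    dead = colsum <= 0
    if np.any(dead):
        m[np.where(dead)[0], np.where(dead)[0]] = 1.0
        colsum = m.sum(axis=0)
    return m / colsum


def _mcl_step(m: np.ndarray, params: MCLParams) -> np.ndarray:
    """One expansion + inflation + pruning round; stays column-stochastic."""
    m = np.linalg.matrix_power(m, params.expansion)
    m = np.power(m, params.inflation)
    m = _normalize_columns(m)
    m[m < params.prune_threshold] = 0.0
    return _normalize_columns(m)


def mcl_matrix(
    sub: LinkerSubnetwork | nx.Graph, params: MCLParams | None = None
) -> tuple[list[str], np.ndarray, bool]:
    """Run the MCL iteration and return (node order, limit matrix, converged)."""
    params = params or MCLParams()
    g = _as_graph(sub)
    if g.number_of_nodes() == 0:
        raise ValueError("empty subnetwork")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    np.fill_diagonal(a, params.self_loop_weight)
    m = _normalize_columns(a)
    converged = False
    for _ in range(params.max_iter):
        m_next = _mcl_step(m, params)
        delta = float(np.max(np.abs(m_next - m)))
        m = m_next
        if delta < params.convergence_tol:
            converged = True
            break
    return nodes, m, converged


def _read_clusters(nodes: list[str], m: np.ndarray) -> list[frozenset[str]]:
    """Interpret the limit matrix as a partition.

    Attractors are nodes with positive return flow (diagonal entries);
    attractor systems are the connected components of the nonzero
    pattern restricted to attractors.  Every node joins the system(s) it
    flows into; a node attracted to several systems joins the largest,
    ties to the system with the lexicographically smallest member.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > 0 or m[j, i] > 0):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    system_of = {i: s for s, comp in enumerate(systems) for i in comp}

    members: list[set[int]] = [set(comp) for comp in systems]
    for j in range(n):
        if j in system_of:
            continue
        pulls = {system_of[i] for i in attractors if m[i, j] > 0}
        if not pulls:
            members.append({j})  # numerically orphaned node: singleton
            continue
        chosen = max(
            pulls,
            key=lambda s: (len(members[s]), ),
        )
        tied = [s for s in pulls if len(members[s]) == len(members[chosen])]
        if len(tied) > 1:
            chosen = min(tied, key=lambda s: nodes[min(members[s])])
        members[chosen].add(j)
    clusters = [frozenset(nodes[i] for i in mem) for mem in members if mem]
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def mcl_cluster(
    sub: LinkerSubnetwork | nx.Graph, params: MCLParams | None = None
) -> ClusterSet:
    """Partition a subnetwork with the Markov Cluster Algorithm.

    Emits a warning and returns the current interpretation (flagged via
    ``converged=False``) if the flow matrix has not settled within
    ``params.max_iter`` rounds.
    """
    params = params or MCLParams()
    nodes, m, converged = mcl_matrix(sub, params)
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iter} iterations; "
            "returning the current cluster interpretation",
            RuntimeWarning,
            stacklevel=2,
        )
    clusters = _read_clusters(nodes, m)
    assert sum(len(c) for c in clusters) == len(nodes)
    return ClusterSet(clusters=clusters, params=params, converged=converged)


def filter_clusters(
    cs: ClusterSet, min_fraction: float = 0.02, report_min_size: int = 20
) -> ClusterSet:
    """Apply the size filters to an MCL partition.

    ``retained`` keeps clusters of size ≥ ceil(min_fraction × total
    nodes) — the denominator is the clustered subnetwork itself.
    Clusters with more than ``report_min_size`` genes are additionally
    flagged for reporting.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    total = cs.n_nodes
    threshold = int(np.ceil(min_fraction * total))
    retained = [c for c in cs.clusters if len(c) >= threshold]
    flagged = [c for c in cs.clusters if len(c) > report_min_size]
    return ClusterSet(
        clusters=cs.clusters,
        params=cs.params,
        converged=cs.converged,
        retained=retained,
        flagged=flagged,
        min_fraction=min_fraction,
        report_min_size=report_min_size,
    )
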