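"""Network proximity of a gene set: shortest paths, core selection, and
the permutation test for the average shortest path.

Differentially expressed genes that act through shared pathways tend to
sit close together in a functional-interaction network.  This module
quantifies that: pairwise hop distances among the seed genes, an
average-linkage dendrogram cut that retains the interconnected core
(the cluster covering at least a configured fraction — 90% by default —
of the seeds), and a permutation test that compares the observed mean
pairwise distance against random gene sets of the same size drawn from
the biggest connected component of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from scipy.spatial.distance import squareform
import networkx as nx

from .network import FINetwork, largest_connected_component, normalize_symbol

__all__ = [
    "DistanceMatrix",
    "CoreSelection",
    "PermutationResult",
    "pairwise_shortest_paths",
    "average_linkage_core",
    "mean_pairwise_distance",
    "permutation_test",
    "permutation_p",
    "replace_infinite",
]

_LOG = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of hop counts among an ordered seed list.

    Entries are non-negative integers stored as floats; disconnected
    pairs are ``inf``; the diagonal is zero.
    """

    seeds: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.seeds), len(self.seeds)):
            raise ValueError("distance matrix shape does not match seed list")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("nonzero diagonal")
        if not np.array_equal(d, d.T):
            raise ValueError("matrix not symmetric")

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.seeds, columns=self.seeds).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass(frozen=True)
class CoreSelection:
    """Seeds retained by the dendrogram cut, with the cut height used."""

    retained: frozenset[str]
    coverage: float
    cut_height: float


@dataclass(frozen=True)
class PermutationResult:
    """Permutation test for the average shortest path of a gene set.

    ``p_value`` uses the add-one estimator (1 + #{null ≤ observed}) /
    (B + 1), so it is bounded below by 1/(B+1) and never exactly zero.
    """

    observed: float
    null_values: tuple[float, ...]
    p_value: float
    B: int
    rng_seed: int
    n_seeds_used: int

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "observed": self.observed,
                    "B": self.B,
                    "p_value": self.p_value,
                    "rng_seed": self.rng_seed,
                    "n_seeds_used": self.n_seeds_used,
                }
            ]
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ----------------------------------------------------------------------


def pairwise_shortest_paths(net: FINetwork, seeds: Sequence[str]) -> DistanceMatrix:
    """Unweighted breadth-first hop distances among the seed genes.

    Disconnected pairs get ``inf``.  Seeds must be network nodes.
    """
    seeds = [normalize_symbol(s) for s in seeds]
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds")
    for s in seeds:
        if s not in net.graph:
            raise KeyError(f"seed gene {s!r} not in network")
    k = len(seeds)
    d = np.full((k, k), np.inf)
    np.fill_diagonal(d, 0.0)
    idx = {s: i for i, s in enumerate(seeds)}
    for s in seeds:
        lengths = nx.single_source_shortest_path_length(net.graph, s)
        i = idx[s]
        for t in seeds:
            if t in lengths:
                d[i, idx[t]] = float(lengths[t])
    return DistanceMatrix(seeds=tuple(seeds), d=d)


def replace_infinite(dm: DistanceMatrix, net: FINetwork) -> DistanceMatrix:
    """Replace infinite entries by (diameter of the largest component + 1).

    Average linkage needs finite dissimilarities; unreachable seed pairs
    are pushed beyond every real distance so they merge last.
    """
    if np.all(np.isfinite(dm.d)):
        return dm
    lcc = largest_connected_component(net)
    fill = float(nx.diameter(lcc.graph)) + 1.0
    d = np.where(np.isfinite(dm.d), dm.d, fill)
    _LOG.info("replaced %d infinite distances by %g", int(np.isinf(dm.d).sum()), fill)
    return DistanceMatrix(seeds=dm.seeds, d=d)


def average_linkage_core(dm: DistanceMatrix, coverage: float = 0.90) -> CoreSelection:
    """Average-linkage dendrogram cut keeping the interconnected core.

    Builds the dendrogram on the hop-distance matrix and cuts at the
    smallest merge height at which the largest cluster covers at least
    ``coverage`` of the seeds; that cluster is returned.  Equal-height
    merges are processed in scipy's deterministic order; a size tie among
    clusters at the cut is broken toward the cluster containing the
    lexicographically smallest seed.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError(
            "distance matrix contains infinities; apply replace_infinite first"
        )
    n = len(dm.seeds)
    if n == 1:
        return CoreSelection(frozenset(dm.seeds), 1.0, 0.0)
    z = linkage(squareform(dm.d, checks=False), method="average")
    heights = np.unique(z[:, 2])
    seeds = np.array(dm.seeds)
    for h in heights:
        labels = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(labels)
        best = sizes.max()
        if best / n >= coverage:
            tied = [
                lab
                for lab in range(len(sizes))
                if sizes[lab] == best
            ]
            members = {lab: sorted(seeds[labels == lab]) for lab in tied}
            chosen = min(tied, key=lambda lab: members[lab][0])
            return CoreSelection(
                retained=frozenset(members[chosen]),
                coverage=best / n,
                cut_height=float(h),
            )
    # the root merge always covers everything
    return CoreSelection(frozenset(dm.seeds), 1.0, float(heights[-1]))


def mean_pairwise_distance(dm: DistanceMatrix) -> float:
    """Mean hop distance over finite unordered off-diagonal seed pairs."""
    iu = np.triu_indices(len(dm.seeds), k=1)
    vals = dm.d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("no finite off-diagonal pair")
    return float(finite.mean())


def permutation_p(observed: float, null_values: Sequence[float]) -> float:
    """Add-one permutation p-value: (1 + #{null ≤ observed}) / (B + 1)."""
    null = np.asarray(null_values, dtype=float)
    if null.size < 1:
        raise ValueError("B must be >= 1")
    return (1.0 + float(np.sum(null <= observed))) / (null.size + 1.0)


def _component_distance_matrix(lcc: FINetwork) -> tuple[list[str], np.ndarray]:
    """All-pairs BFS distances on the largest component (sorted node order)."""
    nodes = sorted(lcc.nodes)
    adj = nx.to_scipy_sparse_array(lcc.graph, nodelist=nodes, format="csr")
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
    return nodes, dist


def permutation_test(
    net: FINetwork,
    seeds: Sequence[str],
    B: int = 1000,
    rng_seed: int = 0,
) -> PermutationResult:
    """Permutation null for the mean pairwise shortest path of a gene set.

    Draws ``B`` uniform without-replacement samples of |seeds| genes from
    the biggest connected component, recomputes the mean pairwise hop
    distance for each, and reports p = (1 + #{null ≤ observed}) / (B + 1).
    Seeds outside the largest component are excluded from the observed
    statistic with a logged count.  Reproducible given ``rng_seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    seeds = [normalize_symbol(s) for s in seeds]
    lcc = largest_connected_component(net)
    nodes, dist = _component_distance_matrix(lcc)
    index = {n: i for i, n in enumerate(nodes)}
    inside = sorted({s for s in seeds if s in index})
    dropped = len(set(seeds)) - len(inside)
    if dropped:
        _LOG.info("excluded %d seed(s) outside the largest component", dropped)
    k = len(inside)
    if k < 2:
        raise ValueError("fewer than 2 seeds inside the largest component")
    if k > len(nodes):
        raise ValueError("more seeds than nodes in the largest component")

    iu = np.triu_indices(k, k=1)
    obs_idx = np.array([index[s] for s in inside])
    observed = float(dist[np.ix_(obs_idx, obs_idx)][iu].mean())

    rng = np.random.default_rng(rng_seed)
    null_values = np.empty(B)
    n = len(nodes)
    for b in range(B):
        pick = rng.choice(n, size=k, replace=False)
        null_values[b] = dist[np.ix_(pick, pick)][iu].mean()
    p = permutation_p(observed, null_values)
    return PermutationResult(
        observed=observed,
        null_values=tuple(float(v) for v in null_values),
        p_value=p,
        B=B,
        rng_seed=rng_seed,
        n_seeds_used=k,
    )
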