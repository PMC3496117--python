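"""Pathway enrichment of network clusters: binomial test + permutation FDR.

Each cluster of size *n* is scored against every pathway gene set with
an upper-tail binomial test: with *p0* the fraction of the background
(all FI-network genes) annotated to the pathway and *k* the overlap,
``p = P(Binomial(n, p0) >= k)``.  The false discovery rate attached to
each observed p-value is estimated by permutation: random gene sets of
size *n* are drawn uniformly from the background, all pathway p-values
recomputed, and the FDR for a cutoff p is the mean number of null
p-values at or below p per permutation divided by the number of observed
p-values at or below p, clipped to [0, 1] and monotonized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import normalize_symbol

__all__ = [
    "PathwayCollection",
    "EnrichmentRow",
    "binomial_enrichment",
    "permutation_fdr",
    "enrich_cluster",
    "read_gmt",
    "write_gmt",
]

_LOG = logging.getLogger(__name__)


class PathwayCollection:
    """Named pathway gene sets intersected with a background universe.

    Pathway genes outside the background are dropped (logged); pathways
    emptied by the intersection are removed.
    """

    def __init__(
        self, pathways: Mapping[str, Iterable[str]], background: Iterable[str]
    ):
        self.background = frozenset(normalize_symbol(g) for g in background)
        if not self.background:
            raise ValueError("empty background universe")
        self.pathways: dict[str, frozenset[str]] = {}
        n_dropped_genes = 0
        for name, genes in pathways.items():
            gs = frozenset(normalize_symbol(g) for g in genes)
            inter = gs & self.background
            n_dropped_genes += len(gs) - len(inter)
            if inter:
                self.pathways[name] = inter
        if n_dropped_genes:
            _LOG.info(
                "dropped %d pathway gene(s) outside the background", n_dropped_genes
            )
        if not self.pathways:
            raise ValueError("no pathway overlaps the background")

    def __len__(self) -> int:
        return len(self.pathways)

    @classmethod
    def from_gmt(cls, path: str | Path, background: Iterable[str]) -> "PathwayCollection":
        return cls(read_gmt(path), background)

    def indicator(self) -> tuple[list[str], list[str], np.ndarray]:
        """(pathway names, sorted background genes, pathways × genes bool matrix)."""
        names = sorted(self.pathways)
        genes = sorted(self.background)
        gene_idx = {g: i for i, g in enumerate(genes)}
        mat = np.zeros((len(names), len(genes)), dtype=bool)
        for r, name in enumerate(names):
            for g in self.pathways[name]:
                mat[r, gene_idx[g]] = True
        return names, genes, mat


@dataclass
class EnrichmentRow:
    pathway: str
    n: int
    k: int
    p0: float
    p_value: float
    fdr: float | None = None


def _binom_upper_tail(k: np.ndarray, n: int, p0: np.ndarray) -> np.ndarray:
    """P(X >= k) for X ~ Binomial(n, p0); k = 0 gives exactly 1."""
    return stats.binom.sf(np.asarray(k) - 1, n, p0)


def binomial_enrichment(
    cluster: Iterable[str], pc: PathwayCollection
) -> list[EnrichmentRow]:
    """Upper-tail binomial enrichment of one cluster against every pathway.

    Rows come back sorted by (p_value, pathway name).
    """
    cluster = frozenset(normalize_symbol(g) for g in cluster)
    if not cluster:
        raise ValueError("empty cluster")
    outside = cluster - pc.background
    if outside:
        raise ValueError(
            f"cluster gene(s) outside the background: {sorted(outside)[:5]}"
        )
    n = len(cluster)
    m = len(pc.background)
    rows = []
    for name in sorted(pc.pathways):
        genes = pc.pathways[name]
        k = len(cluster & genes)
        p0 = len(genes) / m
        p = float(_binom_upper_tail(np.array(k), n, np.array(p0)))
        rows.append(EnrichmentRow(pathway=name, n=n, k=k, p0=p0, p_value=p))
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    return rows


def permutation_fdr(
    observed: Sequence[float],
    pc: PathwayCollection,
    n: int,
    B: int = 1000,
    rng_seed: int = 0,
) -> list[float]:
    """Permutation-based FDR for a list of observed enrichment p-values.

    For each of ``B`` permutations, ``n`` genes are drawn uniformly
    without replacement from the background and all pathway p-values are
    recomputed.  For each observed p:

        fdr(p) = (mean # null p-values ≤ p per permutation)
                 / (# observed p-values ≤ p)

    clipped to [0, 1] and monotonized by a cumulative minimum from the
    largest observed p downward.  The returned list is aligned with
    ``observed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        return []
    names, genes, indicator = pc.indicator()
    n_genes = len(genes)
    if n > n_genes:
        raise ValueError("cluster larger than background")
    sizes = indicator.sum(axis=1)
    p0 = sizes / n_genes

    rng = np.random.default_rng(rng_seed)
    null_p = np.empty((B, len(names)))
    for b in range(B):
        pick = rng.choice(n_genes, size=n, replace=False)
        k = indicator[:, pick].sum(axis=1)
        null_p[b] = _binom_upper_tail(k, n, p0)
    null_flat = np.sort(null_p.ravel())

    order = np.argsort(obs, kind="mergesort")
    fdr = np.empty_like(obs)
    for rank, i in enumerate(order, start=1):
        mean_null = np.searchsorted(null_flat, obs[i], side="right") / B
        fdr[i] = min(1.0, mean_null / rank)
    # monotonize from the largest p downward
    running = 1.0
    for i in order[::-1]:
        running = min(running, fdr[i])
        fdr[i] = running
    return [float(v) for v in fdr]


def enrich_cluster(
    cluster: Iterable[str],
    pc: PathwayCollection,
    B: int = 1000,
    rng_seed: int = 0,
) -> list[EnrichmentRow]:
    """Binomial enrichment plus permutation FDR for one cluster."""
    rows = binomial_enrichment(cluster, pc)
    fdrs = permutation_fdr(
        [r.p_value for r in rows], pc, n=rows[0].n, B=B, rng_seed=rng_seed
    )
    for row, fdr in zip(rows, fdrs):
        row.fdr = fdr
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "n": r.n,
                "k": r.k,
                "p0": r.p0,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in rows
        ]
    )


# ----------------------------------------------------------------------
# GMT dialect (tab-separated: name, description, genes...)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one gene"
                )
            pathways[fields[0]] = [normalize_symbol(g) for g in fields[2:] if g]
    if not pathways:
        raise ValueError(f"{path}: no gene sets found")
    return pathways


def write_gmt(
    pathways: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = sorted(set(normalize_symbol(g) for g in pathways[name]))
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
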