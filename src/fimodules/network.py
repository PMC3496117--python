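"""Functional-interaction (FI) network container, validation and I/O.

The FI network is an undirected simple graph over gene symbols.  It is the
background universe for every statistic in this package: gene-mapping
coverage, the permutation null for network proximity, and the binomial
enrichment background.  Edges may carry an optional annotation
(``activates`` / ``inhibits`` / ``indirect`` / ``unknown``).  Annotations
are preserved through file round trips but ignored by all statistics —
they only style exported diagrams, together with the seed/linker node
roles and up/down expression direction.

Supported dialects
------------------
* edge list — TSV with columns ``gene_a``, ``gene_b`` and an optional
  third ``annotation`` column; ``#`` comment lines and an optional header
  row are skipped.
* SIF — ``geneA fi geneB [geneC ...]``; a single token declares an
  isolated node.  The interaction label is fixed to ``fi`` on export
  (single-relation network).
* GraphML — carries edge annotations plus the ``role`` and ``direction``
  node attributes written by :func:`export_network`.

Gene symbols are case-normalized to upper case on every input path, so
``tnf`` and ``TNF`` are the same node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "FINetwork",
    "GeneMapping",
    "NetworkParseError",
    "normalize_symbol",
    "load_network",
    "largest_connected_component",
    "map_genes",
    "export_network",
]

_LOG = logging.getLogger(__name__)

VALID_ANNOTATIONS = frozenset({"activates", "inhibits", "indirect", "unknown"})
VALID_ROLES = frozenset({"seed", "linker"})
SIF_RELATION = "fi"


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed; names the offending line."""


def normalize_symbol(symbol: object) -> str:
    """Upper-case, whitespace-stripped gene symbol."""
    return str(symbol).strip().upper()


class FINetwork:
    """Undirected simple graph of functional interactions between genes.

    Wraps a :class:`networkx.Graph`.  Invariants enforced at construction:
    no self-loops, no duplicate edges (guaranteed by the nx container),
    every annotated edge exists, and the node set is the union of edge
    endpoints plus declared isolated nodes.
    """

    __slots__ = ("graph",)

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty network")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"self-loops present: {loops[:3]}")
        for u, v, ann in graph.edges(data="annotation"):
            if ann is not None and ann not in VALID_ANNOTATIONS:
                raise ValueError(f"invalid edge annotation {ann!r} on {u}-{v}")
        self.graph = graph

    # -- constructors -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        annotations: Mapping[tuple[str, str], str] | None = None,
    ) -> "FINetwork":
        """Build from an edge iterable, collapsing duplicates and dropping
        self-loops (with a logged count).  ``nodes`` declares isolated nodes.
        """
        g = nx.Graph()
        n_loops = 0
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
        if n_loops:
            _LOG.info("dropped %d self-loop row(s)", n_loops)
        for n in nodes:
            g.add_node(normalize_symbol(n))
        if annotations:
            for (a, b), ann in annotations.items():
                a, b = normalize_symbol(a), normalize_symbol(b)
                if not g.has_edge(a, b):
                    raise ValueError(f"annotation on non-edge {a}-{b}")
                g.edges[a, b]["annotation"] = ann
        return cls(g)

    # -- basic views --------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def edge_annotation(self) -> dict[tuple[str, str], str]:
        return {
            tuple(sorted((u, v))): ann
            for u, v, ann in self.graph.edges(data="annotation")
            if ann is not None
        }

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FINetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.edge_annotation == other.edge_annotation
        )

    def __hash__(self):  # mutable underlying graph; identity hash
        return id(self)

    def __repr__(self) -> str:
        return (
            f"FINetwork({self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges)"
        )

    def subnetwork(self, nodes: Iterable[str]) -> "FINetwork":
        """Induced subgraph on ``nodes`` (must all be present)."""
        nodes = [normalize_symbol(n) for n in nodes]
        missing = [n for n in nodes if n not in self.graph]
        if missing:
            raise KeyError(f"nodes not in network: {missing[:5]}")
        return FINetwork(self.graph.subgraph(nodes).copy())

    def connected_components(self) -> list[frozenset[str]]:
        """Components sorted by decreasing size, ties by smallest member."""
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass(frozen=True)
class GeneMapping:
    """Result of mapping a query gene list onto the FI network.

    ``query_genes`` is the normalized, de-duplicated query (original order
    kept); ``in_network`` the subset found among network nodes.  Coverage
    is therefore invariant to query order and duplicates.
    """

    query_genes: tuple[str, ...]
    in_network: frozenset[str]

    @property
    def coverage_fraction(self) -> float:
        """|in_network| / |query_genes|, reported to 3 decimals."""
        return round(len(self.in_network) / len(self.query_genes), 3)


# ----------------------------------------------------------------------
# loading


def load_network(path: str | Path, dialect: str | None = None) -> FINetwork:
    """Load and validate an FI network from ``path``.

    ``dialect`` is one of ``edgelist``, ``sif``, ``graphml``; when omitted
    it is inferred from the file suffix (``.sif`` / ``.graphml``, anything
    else is read as an edge list).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = {".sif": "sif", ".graphml": "graphml"}.get(
            path.suffix.lower(), "edgelist"
        )
    if dialect == "edgelist":
        return _load_edgelist(path)
    if dialect == "sif":
        return _load_sif(path)
    if dialect == "graphml":
        return _load_graphml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_edgelist(path: Path) -> FINetwork:
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    annotations: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if lineno == 1 and [t.lower() for t in tokens[:2]] == ["gene_a", "gene_b"]:
                continue
            if len(tokens) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected at least 2 gene tokens, "
                    f"got {len(tokens)}"
                )
            a, b = normalize_symbol(tokens[0]), normalize_symbol(tokens[1])
            edges.append((a, b))
            if len(tokens) >= 3 and a != b:
                annotations[tuple(sorted((a, b)))] = tokens[2]
    if not edges and not isolated:
        raise NetworkParseError(f"{path}: no edges found")
    return FINetwork.from_edges(edges, annotations=annotations)


def _load_sif(path: Path) -> FINetwork:
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 1:
                isolated.append(tokens[0])
            elif len(tokens) == 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: SIF row needs source, relation "
                    "and at least one target"
                )
            else:
                src = tokens[0]
                for tgt in tokens[2:]:
                    edges.append((src, tgt))
    if not edges and not isolated:
        raise NetworkParseError(f"{path}: no interactions found")
    return FINetwork.from_edges(edges, nodes=isolated)


def _load_graphml(path: Path) -> FINetwork:
    g = nx.read_graphml(path)
    edges = []
    annotations = {}
    for u, v, data in g.edges(data=True):
        a, b = normalize_symbol(u), normalize_symbol(v)
        edges.append((a, b))
        ann = data.get("annotation")
        if ann:
            annotations[tuple(sorted((a, b)))] = ann
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    return FINetwork.from_edges(edges, nodes=isolated, annotations=annotations)


# ----------------------------------------------------------------------
# operations


def largest_connected_component(net: FINetwork) -> FINetwork:
    """Induced subgraph on the biggest connected component.

    Size ties are broken by the lexicographically smallest member node, so
    the result is deterministic.
    """
    comps = net.connected_components()
    return net.subnetwork(sorted(comps[0]))


def map_genes(net: FINetwork, genes: Sequence[str]) -> GeneMapping:
    """Membership of a query gene list in the network node set.

    Symbols are case-normalized and de-duplicated before matching.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(normalize_symbol(g), None)
    query = tuple(seen)
    in_net = frozenset(g for g in query if g in net.graph)
    return GeneMapping(query_genes=query, in_network=in_net)


def export_network(
    net: FINetwork,
    node_roles: Mapping[str, str] | None = None,
    direction_changes: Mapping[str, float] | None = None,
    path: str | Path = "network",
) -> dict[str, Path]:
    """Write the network as SIF + node-attribute TSV + GraphML.

    ``path`` is a file prefix: ``<path>.sif``, ``<path>_nodes.tsv`` and
    ``<path>.graphml`` are produced, all with deterministic (sorted) row
    order.  ``node_roles`` maps genes to ``seed``/``linker`` (default
    ``seed``); ``direction_changes`` maps genes to a signed log2 fold,
    rendered as ``up``/``down``/``none`` — the red-circle / blue-circle /
    green-diamond styling vocabulary of the exported diagrams.
    """
    path = Path(path)
    node_roles = {normalize_symbol(k): v for k, v in (node_roles or {}).items()}
    direction_changes = {
        normalize_symbol(k): v for k, v in (direction_changes or {}).items()
    }
    for attrs, label in ((node_roles, "role"), (direction_changes, "direction")):
        unknown = [n for n in attrs if n not in net.graph]
        if unknown:
            raise ValueError(f"{label} attribute for unknown node(s): {unknown[:5]}")
    bad_roles = {r for r in node_roles.values() if r not in VALID_ROLES}
    if bad_roles:
        raise ValueError(f"invalid role(s): {sorted(bad_roles)}")

    path.parent.mkdir(parents=True, exist_ok=True)
    nodes = sorted(net.nodes)
    edges = sorted(net.edges)
    ann = net.edge_annotation

    sif_path = path.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        in_edges = {n for e in edges for n in e}
        for a, b in edges:
            fh.write(f"{a}\t{SIF_RELATION}\t{b}\n")
        for n in nodes:
            if n not in in_edges:
                fh.write(f"{n}\n")

    def _direction(n: str) -> str:
        fold = direction_changes.get(n)
        if fold is None or fold == 0:
            return "none"
        return "up" if fold > 0 else "down"

    attr_path = path.parent / (path.stem + "_nodes.tsv")
    with open(attr_path, "w") as fh:
        fh.write("gene\trole\tdirection\n")
        for n in nodes:
            fh.write(f"{n}\t{node_roles.get(n, 'seed')}\t{_direction(n)}\n")

    g = nx.Graph()
    for n in nodes:
        g.add_node(n, role=node_roles.get(n, "seed"), direction=_direction(n))
    for a, b in edges:
        data = {"interaction": SIF_RELATION}
        if (a, b) in ann:
            data["annotation"] = ann[(a, b)]
        g.add_edge(a, b, **data)
    graphml_path = path.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)

    return {"sif": sif_path, "nodes": attr_path, "graphml": graphml_path}
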