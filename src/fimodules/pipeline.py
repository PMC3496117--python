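"""End-to-end orchestration: DE selection through enriched network modules.

Stage order (the run manifest lists these eleven stages)::

    select_de → map_genes → shortest_paths → core_selection →
    permutation_test → infer_linkers → mcl_cluster → filter_clusters →
    binomial_enrichment → permutation_fdr → export_network

Every stage writes a plain-text artifact into the run directory; a JSON
manifest records the package version, configuration (and its hash), the
root RNG seed and per-stage status/timings.  One root seed
deterministically derives an independent substream per randomized stage,
so a run is fully reproducible from its manifest and re-running with
``resume=True`` loads any stage whose artifact is already present under
an identical configuration hash instead of recomputing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import (
    DEGeneSet,
    ExpressionMatrix,
    load_design,
    load_expression,
    select_de_genes,
)
from .enrichment import (
    PathwayCollection,
    enrichment_table,
    binomial_enrichment,
    permutation_fdr,
)
from .linkers import LinkerSubnetwork, infer_linkers
from .mcl import ClusterSet, MCLParams, filter_clusters, mcl_cluster
from .network import (
    FINetwork,
    export_network,
    largest_connected_component,
    load_network,
    map_genes,
)
from .proximity import (
    CoreSelection,
    DistanceMatrix,
    PermutationResult,
    average_linkage_core,
    mean_pairwise_distance,
    pairwise_shortest_paths,
    permutation_test,
    replace_infinite,
)
from .synthetic import SyntheticConfig, write_inputs

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "simulate"]

_LOG = logging.getLogger(__name__)

STAGES = (
    "select_de",
    "map_genes",
    "shortest_paths",
    "core_selection",
    "permutation_test",
    "infer_linkers",
    "mcl_cluster",
    "filter_clusters",
    "binomial_enrichment",
    "permutation_fdr",
    "export_network",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs, thresholds and seeding for an end-to-end run.

    The thresholds default to the study constants: >2-fold change, FDR
    0.05, dendrogram cut covering 90% of seeds, 1,000 permutations,
    MCL inflation 1.6, cluster-size floor at 2% of the subnetwork and
    a 20-gene reporting threshold.
    """

    network: str
    expression: str | None = None
    design: str | None = None
    gene_list: str | None = None  # precomputed DE list, alternative to expression
    gmt: str | None = None
    fc_min: float = 2.0
    fdr_max: float = 0.05
    coverage: float = 0.90
    min_fraction: float = 0.02
    report_min_size: int = 20
    B: int = 1000
    inflation: float = 1.6
    rng_seed: int = 0
    out_dir: str = "run"

    def __post_init__(self) -> None:
        if self.expression is None and self.gene_list is None:
            raise ValueError("need either an expression matrix or a gene list")
        if not (0 < self.coverage <= 1 and 0 < self.min_fraction <= 1):
            raise ValueError("coverage and min_fraction must be in (0, 1]")
        if self.fc_min <= 0 or self.fdr_max <= 0 or self.B < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(rng_seed: int) -> dict[str, int]:
    """Independent per-stage substreams derived from the root seed."""
    rng = np.random.default_rng(rng_seed)
    draws = rng.integers(0, 2**31, size=len(STAGES))
    return {name: int(s) for name, s in zip(STAGES, draws)}


class _Manifest:
    def __init__(self, path: Path, cfg: RunConfig):
        self.path = path
        self.data: dict[str, Any] = {
            "package": "fimodules",
            "version": __version__,
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "rng_seed": cfg.rng_seed,
            "stages": {},
        }

    @staticmethod
    def load(path: Path) -> dict[str, Any] | None:
        if path.exists():
            return json.loads(path.read_text())
        return None

    def record(self, stage: str, status: str, seconds: float, outputs: list[str]):
        self.data["stages"][stage] = {
            "status": status,
            "seconds": round(seconds, 4),
            "outputs": outputs,
        }
        self.write()

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


@dataclass
class RunResult:
    """In-memory view of a finished run."""

    out_dir: Path
    de: DEGeneSet | None
    mapping_coverage: float
    seeds_in_network: frozenset[str]
    core: CoreSelection
    permutation: Any
    subnetwork: LinkerSubnetwork
    clusters: ClusterSet
    enrichment: dict[int, pd.DataFrame]
    manifest: dict[str, Any]


def run_pipeline(cfg: RunConfig, resume: bool = False) -> RunResult:
    """Execute the full analysis; returns the in-memory results.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts of completed stages are left in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out / "run.log")
    manifest = _Manifest(out / "manifest.json", cfg)
    previous = _Manifest.load(out / "manifest.json") if resume else None
    if previous and previous.get("config_hash") != cfg.config_hash():
        _LOG.warning("config hash changed; resume disabled for this run")
        previous = None
    stage_seeds = _stage_seeds(cfg.rng_seed)

    def seeds_for(stage_name: str) -> int:
        return stage_seeds[stage_name]

    def stage(
        name: str,
        compute: Callable[[], Any],
        save: Callable[[Any], list[str]],
        load: Callable[[], Any] | None = None,
    ) -> Any:
        t0 = time.perf_counter()
        prev = (previous or {}).get("stages", {}).get(name)
        if (
            resume
            and load is not None
            and prev
            and prev.get("status") in ("completed", "skipped")
            and all((out / f).exists() for f in prev.get("outputs", []))
        ):
            try:
                result = load()
                manifest.record(
                    name, "skipped", time.perf_counter() - t0, prev["outputs"]
                )
                _LOG.info("stage %s: resumed from artifacts", name)
                return result
            except Exception:  # artifact unreadable → recompute
                _LOG.warning(
                    "stage %s: resume failed, recomputing", name, exc_info=True
                )
        try:
            result = compute()
            outputs = save(result)
        except Exception as exc:
            manifest.record(name, "failed", time.perf_counter() - t0, [])
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, "completed", time.perf_counter() - t0, outputs)
        _LOG.info("stage %s: completed", name)
        return result

    net = load_network(cfg.network)

    # -- 1. DE selection ----------------------------------------------
    if cfg.expression is not None:
        mat = ExpressionMatrix(
            values=load_expression(cfg.expression),
            design=load_design(cfg.design),
        )

        def _compute_de() -> DEGeneSet:
            return select_de_genes(mat, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max)

        def _save_de(de: DEGeneSet) -> list[str]:
            de.write(out / "de_table.tsv")
            return ["de_table.tsv"]

        def _load_de() -> DEGeneSet:
            table = pd.read_csv(out / "de_table.tsv", sep="\t")
            return DEGeneSet(table=table, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max)

        de = stage("select_de", _compute_de, _save_de, _load_de)
        genes_of_interest = sorted(de.selected)
        direction = {g: float(v) for g, v in de.log2fc.items() if g in de.selected}
    else:
        de = None
        genes_of_interest = sorted(
            {
                line.strip().upper()
                for line in Path(cfg.gene_list).read_text().splitlines()
                if line.strip()
            }
        )
        direction = {}
        stage(
            "select_de",
            lambda: genes_of_interest,
            lambda gl: (
                (out / "de_table.tsv").write_text(
                    "gene\n" + "".join(f"{g}\n" for g in gl)
                ),
                ["de_table.tsv"],
            )[1],
        )
    if not genes_of_interest:
        raise PipelineError("stage 'select_de' failed: no genes of interest")

    # -- 2. map onto the network --------------------------------------
    def _save_mapping(m) -> list[str]:
        rows = [
            {"gene": g, "in_network": int(g in m.in_network)} for g in m.query_genes
        ]
        pd.DataFrame(rows).to_csv(out / "gene_mapping.tsv", sep="\t", index=False)
        return ["gene_mapping.tsv"]

    mapping = stage(
        "map_genes", lambda: map_genes(net, genes_of_interest), _save_mapping
    )
    lcc = largest_connected_component(net)
    seeds = sorted(mapping.in_network & lcc.nodes)
    n_outside = len(mapping.in_network) - len(seeds)
    if n_outside:
        _LOG.info("%d mapped gene(s) outside the largest component", n_outside)
    if len(seeds) < 2:
        raise PipelineError(
            "stage 'map_genes' failed: fewer than 2 genes of interest in the "
            "largest network component"
        )

    # -- 3. shortest paths --------------------------------------------
    def _load_dm() -> DistanceMatrix:
        df = pd.read_csv(out / "distance_matrix.tsv", sep="\t", index_col=0)
        return DistanceMatrix(seeds=tuple(df.index), d=df.to_numpy(dtype=float))

    dm = stage(
        "shortest_paths",
        lambda: replace_infinite(pairwise_shortest_paths(net, seeds), net),
        lambda d: (d.write(out / "distance_matrix.tsv"), ["distance_matrix.tsv"])[1],
        _load_dm,
    )

    # -- 4. interconnected core ---------------------------------------
    def _save_core(core: CoreSelection) -> list[str]:
        (out / "core_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(core.retained))
        )
        pd.DataFrame(
            [{"coverage": core.coverage, "cut_height": core.cut_height}]
        ).to_csv(out / "core_summary.tsv", sep="\t", index=False, float_format="%.10g")
        return ["core_genes.txt", "core_summary.tsv"]

    def _load_core() -> CoreSelection:
        genes = frozenset(
            (out / "core_genes.txt").read_text().split()
        )
        summary = pd.read_csv(out / "core_summary.tsv", sep="\t").iloc[0]
        return CoreSelection(
            retained=genes,
            coverage=float(summary["coverage"]),
            cut_height=float(summary["cut_height"]),
        )

    core = stage(
        "core_selection",
        lambda: average_linkage_core(dm, coverage=cfg.coverage),
        _save_core,
        _load_core,
    )
    core_genes = sorted(core.retained)

    # -- 5. permutation test ------------------------------------------
    def _load_perm():
        from .proximity import PermutationResult

        report = pd.read_csv(out / "permutation.tsv", sep="\t").iloc[0]
        null = pd.read_csv(out / "permutation_null.tsv", sep="\t")
        return PermutationResult(
            observed=float(report["observed"]),
            null_values=tuple(null["null_mean_distance"]),
            p_value=float(report["p_value"]),
            B=int(report["B"]),
            rng_seed=int(report["rng_seed"]),
            n_seeds_used=int(report["n_seeds_used"]),
        )

    perm = stage(
        "permutation_test",
        lambda: permutation_test(
            net, core_genes, B=cfg.B, rng_seed=seeds_for("permutation_test")
        ),
        lambda p: (
            p.write(out / "permutation.tsv"),
            pd.DataFrame({"null_mean_distance": p.null_values}).to_csv(
                out / "permutation_null.tsv", sep="\t", index=False,
                float_format="%.10g",
            ),
            ["permutation.tsv", "permutation_null.tsv"],
        )[2],
        _load_perm,
    )

    # -- 6. linkers ----------------------------------------------------
    def _save_sub(sub: LinkerSubnetwork) -> list[str]:
        rows = [{"gene": g, "role": sub.roles[g]} for g in sorted(sub.nodes)]
        pd.DataFrame(rows).to_csv(out / "subnetwork_nodes.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(sub.edges), columns=["gene_a", "gene_b"]).to_csv(
            out / "subnetwork_edges.tsv", sep="\t", index=False
        )
        return ["subnetwork_nodes.tsv", "subnetwork_edges.tsv"]

    def _load_sub() -> LinkerSubnetwork:
        roles = pd.read_csv(out / "subnetwork_nodes.tsv", sep="\t")
        edges = pd.read_csv(out / "subnetwork_edges.tsv", sep="\t")
        return LinkerSubnetwork(
            seeds=frozenset(roles.loc[roles["role"] == "seed", "gene"]),
            linkers=frozenset(roles.loc[roles["role"] == "linker", "gene"]),
            edges=frozenset(
                tuple(sorted((a, b)))
                for a, b in zip(edges["gene_a"], edges["gene_b"])
            ),
        )

    sub = stage(
        "infer_linkers", lambda: infer_linkers(lcc, core_genes), _save_sub, _load_sub
    )

    # -- 7/8. MCL + size filters --------------------------------------
    params = MCLParams(inflation=cfg.inflation)
    clusters_raw = stage(
        "mcl_cluster",
        lambda: mcl_cluster(sub, params),
        lambda cs: (cs.write(out / "clusters_raw.tsv"), ["clusters_raw.tsv"])[1],
    )
    clusters = stage(
        "filter_clusters",
        lambda: filter_clusters(
            clusters_raw,
            min_fraction=cfg.min_fraction,
            report_min_size=cfg.report_min_size,
        ),
        lambda cs: (cs.write(out / "clusters.tsv"), ["clusters.tsv"])[1],
    )

    # -- 9/10. enrichment ---------------------------------------------
    enrichment: dict[int, pd.DataFrame] = {}
    if cfg.gmt is not None and clusters.retained:
        pc = PathwayCollection.from_gmt(cfg.gmt, background=net.nodes)
        cluster_ids = [
            i for i, c in enumerate(clusters.clusters) if c in set(clusters.retained)
        ]

        def _compute_binom():
            return {
                i: binomial_enrichment(clusters.clusters[i], pc) for i in cluster_ids
            }

        def _save_binom(rows_by_cluster) -> list[str]:
            files = []
            for i, rows in rows_by_cluster.items():
                f = f"enrichment_pvalues_cluster{i}.tsv"
                enrichment_table(rows).drop(columns="fdr").to_csv(
                    out / f, sep="\t", index=False, float_format="%.10g"
                )
                files.append(f)
            return files

        rows_by_cluster = stage("binomial_enrichment", _compute_binom, _save_binom)

        def _compute_fdr():
            result = {}
            fdr_seed = seeds_for("permutation_fdr")
            for j, (i, rows) in enumerate(sorted(rows_by_cluster.items())):
                fdrs = permutation_fdr(
                    [r.p_value for r in rows],
                    pc,
                    n=rows[0].n,
                    B=cfg.B,
                    rng_seed=(fdr_seed + j) % 2**31,
                )
                for r, v in zip(rows, fdrs):
                    r.fdr = v
                result[i] = enrichment_table(rows)
            return result

        def _save_fdr(tables) -> list[str]:
            files = []
            for i, table in tables.items():
                f = f"enrichment_cluster{i}.tsv"
                table.to_csv(out / f, sep="\t", index=False, float_format="%.10g")
                files.append(f)
            return files

        enrichment = stage("permutation_fdr", _compute_fdr, _save_fdr)
    else:
        stage("binomial_enrichment", lambda: None, lambda _: [])
        stage("permutation_fdr", lambda: None, lambda _: [])
        enrichment = {}

    # -- 11. export ----------------------------------------------------
    def _export():
        subnet = net.subnetwork(sub.nodes)
        return export_network(
            subnet,
            node_roles=sub.roles,
            direction_changes={g: v for g, v in direction.items() if g in sub.nodes},
            path=out / "subnetwork",
        )

    stage(
        "export_network",
        _export,
        lambda files: [Path(f).name for f in files.values()],
    )

    manifest.write()
    return RunResult(
        out_dir=out,
        de=de,
        mapping_coverage=mapping.coverage_fraction,
        seeds_in_network=frozenset(seeds),
        core=core,
        permutation=perm,
        subnetwork=sub,
        clusters=clusters,
        enrichment=enrichment,
        manifest=manifest.data,
    )


def simulate(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic input bundle consumable by run_pipeline."""
    return write_inputs(cfg, out_dir)


def _setup_run_logging(logfile: Path) -> None:
    root = logging.getLogger("fimodules")
    root.setLevel(logging.INFO)
    have = {
        getattr(h, "baseFilename", None)
        for h in root.handlers
        if isinstance(h, logging.FileHandler)
    }
    if str(logfile) not in have:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        root.addHandler(fh)
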