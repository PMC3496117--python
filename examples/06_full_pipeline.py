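"""End-to-end run: synthetic inputs through enriched network modules.

Equivalent to the CLI:  fimodules simulate ... && fimodules run ...
Writes every stage artifact plus a manifest into the run directory.
"""

from fimodules.pipeline import RunConfig, run_pipeline, simulate
from fimodules.synthetic import SyntheticConfig

inputs = simulate(SyntheticConfig(rng_seed=1), "scratch/example_run/inputs")

cfg = RunConfig(
    network=str(inputs["network"]),
    expression=str(inputs["expression"]),
    design=str(inputs["design"]),
    gmt=str(inputs["gmt"]),
    B=1000,
    rng_seed=1,
    out_dir="scratch/example_run/out",
)
result = run_pipeline(cfg)

print(f"run directory: {result.out_dir}")
print(f"DE genes selected:    {len(result.de.selected)}")
print(f"network coverage:     {100 * result.mapping_coverage:.1f}%")
print(f"core genes retained:  {len(result.core.retained)}")
print(f"proximity p-value:    {result.permutation.p_value:.4g}")
print(f"subnetwork:           {len(result.subnetwork.nodes)} genes "
      f"({len(result.subnetwork.linkers)} linkers)")
print(f"clusters retained:    {len(result.clusters.retained)}")
for cid, table in sorted(result.enrichment.items()):
    best = table.sort_values(['p_value', 'pathway']).iloc[0]
    print(f"  cluster {cid}: top pathway {best['pathway']} "
          f"(p={best['p_value']:.2g}, fdr={best['fdr']:.2g})")
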