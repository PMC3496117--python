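"""Generate a synthetic study bundle with known ground truth.

Writes the four input files the pipeline consumes (interactome edge
list, expression matrix, sample design, pathway GMT) plus a ground-truth
manifest, then prints what was planted.
"""

from fimodules.synthetic import SyntheticConfig, write_inputs

cfg = SyntheticConfig(rng_seed=1)
paths = write_inputs(cfg, "scratch/example_inputs")

print("written files:")
for name, path in paths.items():
    print(f"  {name:14s} {path}")

from fimodules.synthetic import GroundTruth

truth = GroundTruth.from_json(paths["ground_truth"])
print(f"\nplanted modules: {len(set(truth.planted_module_labels.values()))}")
print(f"planted DE genes: {len(truth.planted_de_genes)} "
      f"(each carries a ±{cfg.log2_effect} log2 line effect, "
      f"i.e. a {2**cfg.log2_effect:.1f}-fold change)")
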