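"""Test whether a gene set clusters in the interactome.

Computes pairwise hop distances among the genes of interest, selects the
interconnected core with an average-linkage dendrogram cut, and runs the
permutation test for the average shortest path against random gene sets
of the same size from the biggest connected component.
"""

import numpy as np

from fimodules import (
    average_linkage_core,
    mean_pairwise_distance,
    pairwise_shortest_paths,
    permutation_test,
    replace_infinite,
)
from fimodules.synthetic import SyntheticConfig, generate_network

cfg = SyntheticConfig(rng_seed=1)
net, truth = generate_network(cfg)
seeds = sorted(truth.planted_de_genes)

dm = replace_infinite(pairwise_shortest_paths(net, seeds), net)
core = average_linkage_core(dm, coverage=0.90)
print(f"seeds: {len(seeds)}; core retained {len(core.retained)} "
      f"({100 * core.coverage:.0f}%) at dendrogram height {core.cut_height:.2f}")
print(f"mean pairwise hop distance: {mean_pairwise_distance(dm):.3f}")

res = permutation_test(net, sorted(core.retained), B=1000, rng_seed=7)
print(f"permutation null mean:      {np.mean(res.null_values):.3f}")
print(f"p-value (B={res.B}):         {res.p_value:.4g}")
print("\nA small p means the gene set sits far closer together in the")
print("network than equally sized random gene sets — pathway-level signal.")
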