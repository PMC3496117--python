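"""Score a network cluster against pathway gene sets.

Upper-tail binomial test per pathway, with a permutation-based FDR from
random gene draws out of the whole network background.
"""

from fimodules import enrich_cluster, filter_clusters, infer_linkers, mcl_cluster
from fimodules.synthetic import SyntheticConfig, generate_network, generate_pathways

cfg = SyntheticConfig(rng_seed=1)
net, truth = generate_network(cfg)
pathways = generate_pathways(net, truth, n_decoy=20, rng_seed=1)

sub = infer_linkers(net, sorted(truth.planted_de_genes))
clusters = filter_clusters(mcl_cluster(sub))
cluster = max(clusters.retained, key=len)
print(f"scoring the largest retained cluster ({len(cluster)} genes) "
      f"against {len(pathways)} pathways\n")

rows = enrich_cluster(sorted(cluster), pathways, B=1000, rng_seed=11)
print(f"{'pathway':22s} {'k/n':>6s} {'p0':>6s} {'p':>10s} {'fdr':>6s}")
for r in rows[:6]:
    print(f"{r.pathway:22s} {r.k:3d}/{r.n:<3d} {r.p0:6.3f} "
          f"{r.p_value:10.3g} {r.fdr:6.3f}")
print("\nThe planted module's own pathway should rank first with a tiny")
print("binomial p and FDR near 0; decoy sets should look unremarkable.")
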