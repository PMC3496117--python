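# Methods

## Scope and data model

`fimodules` analyses a gene list (or a genes × samples intensity matrix
plus design table) against an undirected functional-interaction (FI)
network. The FI network is treated purely as a connectivity substrate:
optional edge annotations (activating / inhibitory / indirect) are
preserved through file round trips and exported for network viewers,
but no statistic uses them. Gene symbols are upper-cased before any
matching, since array annotation files mix symbol cases freely.

## Differential expression

Per gene the model is a fixed-effects ANOVA on the log2 scale:

    log2(intensity) = μ + line + dye + array + ε,   ε ~ N(0, σ²)

with `line` the biological contrast (resistant vs control) and `dye`
and `array` the nuisance factors of a two-color hybridization.
Interactions are omitted: with the small sample sizes typical of these
designs there are too few residual degrees of freedom to support them,
and the synthetic generator's data-generating process is additive by
construction. The model is fitted by ordinary least squares; on
balanced designs (which the generator always emits) the OLS estimates
coincide with the moment estimators used by commercial array suites, so
nothing is lost by the simpler fit. The line coefficient is the log2
fold change (resistant minus control; `control` is the reference level
when present, otherwise the lexicographically smaller level) and the
line term's F-test provides the p-value. All genes share one design
matrix, so the whole matrix is fitted with a single least-squares
solve.

Degenerate inputs: a gene with zero residual variation gets p = 1 when
the line contrast is also null (a constant gene) and p = 0 when it is
not (a noiseless planted effect); "zero" is judged relative to the
gene's total sum of squares (factor 1e-12). Duplicate gene symbols
(multi-probe genes) collapse to the row with the largest |log2fc|
before multiple-testing correction.

Selection applies two filters: |fold change| > `fc_min` (linear fold,
default 2.0) and Benjamini–Hochberg q ≤ `fdr_max` (default 0.05; 0.01
gives a stricter list). The BH step-up is delegated to statsmodels and
cross-checked in the tests against a direct enumeration of the step-up
definition.

## Network proximity

Distances are unweighted hop counts (breadth-first search); pairs in
different components are infinite. For the dendrogram these infinities
are replaced by (diameter of the largest component + 1), so unreachable
genes merge last. The average-linkage dendrogram is cut at the smallest
merge height at which the largest cluster covers at least `coverage`
(default 0.90) of the genes, and that single largest cluster is the
retained core. A size tie at the cut goes to the cluster containing
the lexicographically smallest gene. Choosing one cluster (rather than
a union of clusters reaching 90%) is a deliberate, simpler reading of
the "core" idea; with tightly clustered inputs the two coincide.

The permutation test draws `B` (default 1,000) gene sets of the same
size, uniformly without replacement, from the biggest connected
component only, and recomputes the mean pairwise distance for each.
Genes of interest outside that component are excluded from the observed
statistic with a logged count. The p-value uses the add-one estimator
(1 + #{null ≤ observed}) / (B + 1): it is never exactly zero, is
bounded below by 1/(B+1), and is conservative under ties. For speed
the implementation computes the component's all-pairs distance matrix
once (scipy csgraph BFS) and evaluates each draw by submatrix
averaging; 1,000 draws on a few-hundred-node component take well under
a second.

## Linker inference

Connecting k seed genes with the fewest extra nodes is the node-
weighted Steiner problem, which is NP-hard; the classical heuristic —
minimum spanning tree of the seed-to-seed hop-distance graph, each tree
edge expanded into a concrete shortest path — is used as the skeleton.
Three refinements close the gap to optimality on small instances
without changing the asymptotics:

* path expansion prefers, among equal-length shortest paths, the one
  using the fewest nodes not already selected (dynamic program over
  BFS layers), with remaining ties going to the lexicographically
  smallest node sequence;
* redundant linkers — those whose removal keeps all seeds connected —
  are pruned in sorted order to a fixed point;
* a local search tries inserting single nodes, then adjacent node
  pairs, from the solution's neighborhood and re-prunes; an insertion
  is kept when it lowers the linker count. This captures star-type
  Steiner points (one hub replacing several path nodes) that no
  tree-over-pairwise-paths construction can express.

Against exhaustive Steiner-node search on several hundred random
12-node instances the refined heuristic matched the optimum in every
case. All tie-breaks are deterministic (sorted order), so identical
inputs give identical subnetworks. The final subnetwork keeps *all*
network edges among the selected nodes, not only tree paths — module
density is real signal for the clustering stage, and exported diagrams
should show it.

## Markov clustering

MCL is implemented from scratch on dense numpy matrices — adequate for
subnetworks up to a few thousand nodes, which is the regime this
pipeline clusters (whole-interactome MCL is out of scope). The
iteration: add self-loops of weight 1, column-normalize; then
repeatedly (a) expansion — square the matrix, (b) inflation — raise
entrywise to `inflation` (default 1.6) and renormalize columns,
(c) prune entries below 1e-5 and renormalize. Convergence is declared
when the largest entry change drops below 1e-6; the column sums stay
at 1 (±1e-9) throughout, which the tests assert. Non-convergence
within `max_iter` (default 200) produces a warning and the current
interpretation, flagged in the output.

Clusters are read off the limit matrix as attractor systems (nodes with
positive return flow, merged when they exchange flow); every other node
joins the system it flows into. A node attracted to several systems —
rare, arising from symmetric inputs — joins the larger cluster, with
ties going to the cluster holding the lexicographically smallest
member, making the partition deterministic and exhaustive.

Size filters: clusters of at least ⌈`min_fraction` × subnetwork size⌉
nodes are retained (default 2%; the denominator is the clustered
subnetwork, not the whole interactome), and clusters above
`report_min_size` (default 20) are flagged for individual reporting.

Inflation controls granularity: at 1.6 on a scale-free graph MCL is
deliberately coarse, and planted modules embedded in a large backbone
can be absorbed into backbone-dominated clusters. That is a property
of the parameterization, not a defect; the pipeline avoids it by
clustering the linker-augmented subnetwork, where the recovered
modules separate cleanly (adjusted Rand index 1.0 across the benchmark
seeds).

## Pathway enrichment

For a cluster of size n and a pathway covering fraction p₀ of the
background (all FI-network genes — not the array's universe), the
enrichment p-value is the upper binomial tail P(X ≥ k) with k the
overlap; the "≥ k" convention is the standard enrichment reading.
Pathway gene sets are read from GMT and intersected with the background
up front (dropped genes logged).

The permutation FDR recomputes all pathway p-values for `B` random
draws of n background genes. For an observed p, the estimate is
(mean number of null p-values ≤ p per permutation) / (number of
observed p-values ≤ p), clipped to [0, 1] and monotonized by a
cumulative minimum from the largest p downward — the plug-in ratio
estimator; the permutation scheme fixes the null, the estimator is the
conventional choice. Draws are uniform over the background and do not
preserve degree structure; a degree-matched null would be stricter for
hub-heavy clusters and is a known limitation.

## Synthetic data generator

The generator emulates the study design end to end with known ground
truth, under these default conditions: a 300-gene interactome grown by
preferential attachment (m = 2), matching the heavy-tailed degree
distribution of real interactomes (permutation nulls and MCL both
behave differently on heavy-tailed graphs than on Erdős–Rényi ones, so
the tests should run on realistic topology); three planted modules of
20, 20 and 15 genes whose internal pairs are wired with probability
0.6 (far above the ~1.3% backbone density); 12 DE genes planted per
module with a ±1.5-log2 line effect (≈2.8-fold, comfortably beyond the
2-fold filter) and random sign; log2-scale Gaussian noise σ = 0.3; a
dye offset of 0.2 and per-array offsets with SD 0.1; and six
dye-swapped two-color arrays (12 sample channels, 4 residual degrees
of freedom in the ANOVA). Intensities are 2^(log2 model), hence
strictly positive, and the design is balanced by construction — which
is what makes the OLS reading of the DE model exact.

Planting DE genes inside dense modules creates the phenomenon the
pipeline is built to detect: tightly linked DE genes occupying a small
corner of the network. A `random` placement mode scatters the DE genes
uniformly instead, as a negative control (linkers appear, proximity
weakens). All outputs are reproducible bit-for-bit from `rng_seed`.

What the generator does **not** emulate: probe-level artifacts, spatial
or intensity-dependent dye bias (no loess/quantile normalization is
implemented or needed), correlated noise between co-expressed genes,
annotation errors, or the incomplete coverage of real interactomes.
Passing tests therefore demonstrate the statistical machinery under the
stated model, not robustness to those real-data complications.

## Pipeline and reproducibility

The eleven stages run in a fixed order (DE selection → mapping →
distances → core → permutation test → linkers → MCL → size filters →
binomial enrichment → permutation FDR → export). One root seed
deterministically derives an independent substream per randomized
stage, so stages are individually reproducible. Every stage writes a
plain-text artifact; the JSON manifest records version, configuration
hash, seed and per-stage status/timings. Re-running with `resume=True`
loads artifacts of completed stages (same configuration hash) instead
of recomputing. Stage TSV/SIF/GraphML outputs are byte-identical
across reruns with the same configuration and seed; the manifest and
log carry wall-clock timings and are excluded from that guarantee.

Benchmark problem sizes used in the test suite — 300-gene networks,
20 generator seeds, 500 calibration replicates at B = 200, 100 random
graphs for the shortest-path oracle, 20 twelve-node Steiner instances —
were chosen to give stable pass/fail decisions at desk scale while the
full suite stays fast.

## Known limitations

* The FDR permutation null ignores network degree structure (uniform
  draws, as specified by the procedure).
* The core selection takes a single dendrogram cluster; inputs whose
  interconnected core is genuinely bimodal would lose one lobe.
* MCL is dense; genome-scale graphs would need a sparse variant.
* The DE stage assumes a near-balanced design; strongly unbalanced
  designs would re-open the gap between moment and OLS estimators.
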