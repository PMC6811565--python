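# Methods

This note records the models, the parameter choices that matter, the
numerical conventions, and what the synthetic benchmarks do and do not show.

## Network construction

**Adjacency.** Signed weighted adjacency `A_ij = (0.5 + 0.5·cor(x_i, x_j))^β`
with Pearson correlation across samples (not biweight midcorrelation).
Correlation −1 maps to adjacency 0, so anti-correlated genes never share a
module. Constant genes are an error — the correlation is undefined and the
caller should filter or fix the input.

**Soft threshold.** For each candidate β (default 1..30) the connectivities
`k_i = Σ_{u≠i} a_iu` are binned into 10 equal-width bins and
log10(bin frequency) is regressed on log10(bin mean k); the smallest β whose
R² reaches 0.8 is shared across all tissues (the β of the worst-fitting
tissue when scanning per tissue), since a single network regime is needed
for the consensus to be comparable. If no candidate reaches the threshold
the best-fitting one is used and flagged. A flat frequency profile (no
power-law signal) scores R² = 0.

**TOM.** Weighted topological overlap
`TOM_ij = (Σ_{u∉{i,j}} a_iu·a_ju + a_ij) / (min(k_i,k_j) − a_ij + 1)`
with unit diagonal, computed by matrix multiplication and verified against a
triple-loop evaluation to 1e-10 in the tests. A `binary` variant thresholds
the adjacency at 0.5 first; the weighted form is the default everywhere.

**Consensus orientation.** The consensus is the elementwise **minimum over
TOM similarities**, converted to a dissimilarity afterwards: a gene pair is
consensus-similar only when strongly co-expressed in every tissue. Taking
the minimum over dissimilarities instead would mark a pair similar if *any*
tissue co-expresses it — the opposite of "preserved across all tissues" —
and is available behind `literal_min_dissim` for comparison only.

**Module detection.** Average-linkage hierarchical clustering of the
consensus dissimilarity; branches below `cut_height_fraction` (default
0.995) × the maximum merge height are candidates; candidates smaller than
`min_module_size` (default 30) dissolve. A medoid-style stage then adopts
an unassigned gene into the module with the smallest average dissimilarity
to its members, but only if (a) that average beats the gene's average
dissimilarity to all assigned genes and (b) it lies below the cut height.
Condition (b) is essential: without it, a pure-noise gene is almost surely
slightly closer to one module than to the average module and the whole
background gets absorbed (measured: planted-module Jaccard drops from ~1.0
to ~0.14 on the standard benchmark). `deep_split` is accepted for interface
parity with the dynamic hybrid tree cut but the static cut here is governed
by `cut_height_fraction` alone.

## Stability

`drop10` removes ⌈0.1·M⌉ samples without replacement; `resample` draws M
samples with replacement (duplicate ids suffixed `.1`, `.2`, …). The whole
consensus clustering is rerun per repetition with the reference β — the
perturbation changes samples, not the network regime, so rescanning β would
only add noise. Preservation is best-match overlap: each reference module
claims the perturbed module with the largest intersection (unassigned
ineligible); the preserved fraction is claimed overlap / assigned reference
genes. This statistic is invariant under relabeling of either partition.

## Eigengenes, meta-modules, preservation

A module eigengene is the first right singular vector of the standardized
member-gene submatrix, rescaled to unit variance and oriented so the mean
correlation with member genes is positive (exact ties: positive first
loading). Eigengene networks use soft threshold 1. Meta-modules: classical
(Torgerson) MDS of the consensus eigengene dissimilarity into 2 dimensions,
then k-means with 50 seeded restarts keeping the best inertia; k is a fixed
input (the analysis drivers use the number of planted groups; on real data
it is a modelling choice). Meta-module eigengenes are computed from the
union of member genes by default; an eigengene-of-eigengenes variant is
available behind a flag and matters only when the members disagree.

Preservation of two networks: `Preserv = 1 − |a¹ − a²|` elementwise (the
range `1 − (max − min)` for more than two), scaled connectivity
`C_i = 1 − Σ_{j≠i}|a¹_ij − a²_ij|/(n−1)` and density `D` = the same sum over
all ordered pairs. `D = mean(C)` is an algebraic identity and is asserted to
1e-12; all quantities stay in [0, 1] for inputs in [0, 1].

## Trait association and the disease signature

GS is the absolute Pearson correlation with the 0/1 phenotype
(point-biserial; any affine encoding gives the same value). GC is the
weighted degree restricted to the gene's own module, with unassigned genes
scored over the unassigned pool. Consensus = per-gene median across tissues
(even counts: midpoint). The GS–GC correlation within a meta-module uses the
t-distribution p-value with n−2 degrees of freedom; this p is
anticonservative under the null because member genes share the tissue
factor, so the per-module calls should be read as a ranking device — on the
synthetic benchmark the trait-shifted module separates from the null modules
by a wide margin in r.

The disease signature takes genes at or above the `quantile` (default 0.8)
cutoffs of *both* consensus GS and consensus GC, computed within the
meta-module with linear interpolation, then maps them onto the interactome.

## Network pharmacology

Distances are unweighted shortest paths on the interactome, computed with
sparse multi-source traversals. S is the largest connected component of the
induced signature subgraph; ⟨d_s⟩ averages each signature protein's distance
to its nearest other signature protein (unreachable proteins excluded and
logged; the default interactome is restricted to its largest connected
component so this is moot). ⟨d_c⟩ averages each mapped drug target's
distance to the nearest signature protein.

**Degree-preserving nulls.** Nodes are binned by increasing degree, runs of
equal degree kept together, adjacent bins merged until each holds
`min_bin_size` nodes (default 100; the synthetic benchmarks use 25 on their
smaller graphs); each reference node is replaced by a uniform draw without
replacement from its bin, widening to neighboring bins if exhausted. With
singleton bins the degree multiset is preserved exactly. Known limitation:
for a reference containing the graph's extreme hubs the top bin's mean
degree lies below the hubs' own degrees, so the null is slightly biased
toward lower-degree (hence more distant) nodes on heavy-tailed graphs; this
is a generic property of degree-binned randomization, mild at the bin sizes
used. z-scores use the population σ (divide by n_reps); the empirical p is
the fraction of null samples at least as extreme in the observed direction.

**Screening.** For each drug the null replaces *both* the target set and the
disease signature with degree-matched samples of the same sizes. Within one
repetition the random signature is shared across all drugs (each drug still
draws its own random targets), so one multi-source traversal serves the
whole catalogue per repetition; each drug's null is marginally correct, and
nulls across drugs are positively correlated, which does not affect
per-drug z-scores. Top-list eligibility uses the lower `dc_quantile` of all
screened ⟨d_c⟩ (default 5%, the convention for a ~2000-drug catalogue; the
40-drug synthetic screens use 50% so the eligible pool is not smaller than
the list length); ranking is by ascending z with ties broken by ⟨d_c⟩ then
drug id, making the output independent of input order.

**Fisher tests.** 2×2 tables are evaluated by exact enumeration over all
tables with the observed margins (hypergeometric point probabilities);
two-sided p sums the probabilities ≤ the observed one with 1e-12 relative
slack. The catalogue-wide comparison treats the top list and the catalogue
as two independent groups; `min_relevant_count` scans how relevant the
catalogue would have to be before a 9-of-10 top list loses significance.

## Synthetic data: what it emulates and what it does not

Each planted module is a one-factor model: gene g has loading u_g drawn
uniformly in [0.8√w, min(1, 1.2√w)] for target within-correlation w, and
expression `u_g·f + √(1−u_g²)·ε`. The module eigengene is the factor itself,
analytically. Disease modules add `trait_shift` (default study condition:
1.2 factor SDs — strong but realistic for a hub-driven disease module; it
yields hub–trait correlations around 0.5) to the factor in affected samples,
so hub genes are the most trait-correlated — exactly the structure the
GS–GC correlation detects. Membership is shared across tissues; factors are
redrawn per tissue.

The interactome is preferential-attachment growth (heavy-tailed degrees);
the disease neighborhood is a breadth-first ball around a high-degree node,
connected by construction. Proximal drugs target the neighborhood and its
direct neighbors, distal drugs target nodes at distance ≥ 3.

Not emulated: probe/batch effects, RNA-seq count noise, correlated
background genes, overlapping modules, protein complexes or edge
confidence on the interactome, and polypharmacology beyond random target
sets. Passing the recovery benchmarks therefore shows the machinery is
correct and well calibrated on clean planted structure, not that any
particular real dataset will yield stable modules.

## Benchmark scales

The standard study conditions: 4 tissues × 1000 genes × (20+20) samples
with three planted 50-gene modules at within-correlation 0.6; a 5000-node
interactome (3 edges per new node) with a 25-node neighborhood and 20+20
drugs of 3 targets; 1000-repetition nulls; stability over 10 repetitions
per mode. The analysis drivers use a 2000-node interactome and 300–500
repetition nulls to keep the narrative run short; all statistics scale in
the obvious way.
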