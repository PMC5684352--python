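# Methods

## Data model

A layer is a binary m × p incidence matrix `B` between two guilds (rows, e.g.
Lepidoptera; columns, e.g. plants) with unique species labels. Two layers are
analysed as an aligned pair over the union of the species seen in either
source: a species recorded in only one layer is carried as an all-zero
row/column in the other, so that "interacts in only one layer" is an explicit
state every downstream statistic sees. Label matching is exact and
case-sensitive by default (a `normalize_labels` option lowercases and strips
whitespace); taxonomic reconciliation is expected to happen upstream. Any
weight column in the input is thresholded at > 0 with a warning — the method
operates on presence/absence. The three-block node order of the full
multilayer adjacency (guild-A of layer 1, shared guild, guild-A of layer 2)
is fixed for export reproducibility.

## Degree co-distribution

For a chosen guild, the paired degrees `(u, w)` of every species across the
two layers are cross-tabulated at the **raw observed integer degree levels**
(no binning; a binned view can be derived from the exported table). Levels are
ascending; only attained levels enter the table, so no expected cell is zero.
Zero-degree species occupy the degree-0 classes — on real data these
no-interaction classes are typically among the most prominent cells.

Independence of the two margins is tested with the plain Pearson chi-square
(no continuity correction), `df = (levels_u − 1)(levels_w − 1)`. Because raw
degree levels produce sparse tables, the asymptotic p-value is flagged with a
warning when more than 20% of expected counts fall below 5, and a seeded
Monte-Carlo p-value over tables drawn with both margins fixed (Patefield
sampling via `scipy.stats.random_table`, add-one correction) is available and
recommended for such tables; asymptotic remains the default reporting
convention. Per-cell Pearson residuals are exported in long format with
shading tiers fixed at |r| ≥ 2 (≈ α = 0.05) and |r| ≥ 4 (≈ α = 0.0001), signs
giving over-/under-representation, and zero-count cells flagged so a renderer
can distinguish them from small frequencies. A minimal matplotlib mosaic
renderer is included; the TSV is the primary product.

## Module detection

Each layer is clustered on its symmetric (m+p) × (m+p) adjacency
`U = [[0, B], [Bᵀ, 0]]` by Newman's leading-eigenvector method — standard
unipartite modularity on the bipartite adjacency, not Barber's bipartite
variant, matching how the method is usually applied with general-purpose
graph libraries. Isolated nodes are split off as singleton modules first;
connected components are then bisected recursively: for the current group `g`
the generalized modularity matrix `B(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik` with
`B_ij = A_ij − k_i k_j / 2M` is formed, and the group splits along the sign
of the leading eigenvector only if the leading eigenvalue exceeds `tol`
(default 1e-10) **and** the split strictly increases Q (gains ≤ 1e-12 count
as none). Eigenvector components that are exactly zero join the positive
side. Determinism: groups of ≤ 256 nodes use a dense symmetric eigensolver;
larger groups use Lanczos with a fixed start vector and a dense fallback on
non-convergence. Partitions are returned in canonical form (ids by decreasing
module size, ties by lexicographically smallest member), so identical inputs
give identical output byte-for-byte.

An optional Kernighan–Lin style refinement (`fine_tune=True`) sweeps single
nodes across the bisection boundary after each spectral split, keeping the
best intermediate state and repeating until no pass improves. The default is
the bare spectral method (lowest cost, and the variant reference
implementations share); the refinement markedly improves recovery of planted
structure — on the 60×60 4-block benchmark below the bare method reaches
NMI ≥ 0.9 against the planted truth in only ~28% of seeds versus ~99% with
refinement, because the spectral bisection strands a few boundary nodes —
so recovery benchmarks and quality-critical analyses should enable it.
Known limitation: like all modularity maximization, the method has a
resolution limit and the heuristic carries no optimality guarantee; tests
assert it beats the connected-components baseline and random partitions, not
the exhaustive optimum.

## Module-composition similarity

The confusion matrix `N_ij` counts species shared by module `i` of one layer
and module `j` of the other, over the **full species set** including
zero-degree singletons (an option restricts to species interacting in both
layers for sensitivity analysis). The normalized mutual information is the
Danon confusion-matrix form; natural logarithms are used (the base cancels),
`0·log 0 = 0`, and the degenerate case where both partitions are the trivial
single module returns 1 (they coincide; a one-sided trivial partition yields
0 through the formula itself). Note that NMI is not monotone under module
merges: merging two modules with identical partner profiles leaves the mutual
information unchanged but shrinks the entropy normalizer, so `I` can rise.
The module co-structure is also exported as a bipartite module graph
(GraphML/TSV) whose edge weights are shared-species counts — the
visual companion to `I`, since intermediate NMI values are hard to interpret
on their own.

## Configuration-model null

The null hypothesis is that module-composition similarity is whatever the two
degree sequences force. Layers are randomized with the **curveball**
algorithm: a trade picks two rows, fixes their shared partners, and randomly
re-splits their exclusive partners preserving both set sizes; every trade and
hence every sample preserves all row and column sums exactly. Rows are the
traded guild (trading columns samples the same ensemble). The default trade
count is 5 × m per randomization, a standard mixing allowance; on small
enumerable instances the sampler is statistically uniform over the
fixed-margin ensemble (chi-square uniformity tests in the suite). Per
replicate, both layers are independently randomized, modules are re-detected
with the observed run's settings, and `I` is recomputed; 999 replicates by
default. Empirical p-values use the add-one convention
`p = (1 + #extreme)/(1 + n)` with ties counted in both tails; `p_ge` (is the
observed similarity *higher* than the null's?) is the headline test, with
`p_le` and `p_two` reported alongside since either direction can be of
interest. All replicate streams derive from one seed via spawned
`SeedSequence` children, so reports are byte-identical across reruns.

## Synthetic generator

`planted_pair` emulates the structure the analysis targets: layer 1 is a
k-block bipartite stochastic block model (blocks as equal as possible,
remainders to the leading blocks; defaults 60 + 60 species, k = 4,
p_in = 0.4, p_out = 0.02 — dense enough within blocks for the structure to be
detectable, sparse enough between to resemble ecological modularity); layer 2
keeps each species' block with probability `congruence` (default 0.9) and
redraws the rest uniformly, then an optional fraction of rows is zeroed to
emulate species active in only one layer (set ≈ 0.46 to mimic the visitation
side of the empirical Lepidoptera data). Planted partitions mark zero-degree
species as singletons, mirroring the detector's convention.
`degree_matched_pair` realizes exact degree sequences (Gale–Ryser feasibility
check, greedy constructive fill, curveball shuffles for uniformization).

What the generator does **not** emulate: the heavy right-skewed degree
distributions of real interaction webs (hubs with hundreds of partners),
guild-size asymmetry, and sampling effort artefacts. Passing tests therefore
demonstrate correctness of the machinery and its calibration under
block-structured sparsity, not performance claims on empirical data.

## Problem sizes and numerical choices

The test suite and the acceptance runner work at the generator's default
scale (120-node layers; 999 null replicates for the headline run; 50 seeds
for recovery; 200 datasets × 99 replicates, 12×12 three-block layers, for the
p-value-calibration experiment; 500 simulated tables × 199 Monte-Carlo draws
for chi-square calibration) — sizes at which the calibration bands
(binomial 3σ) are informative while a full run stays in the minutes range.
Calibration experiments are seeded and their acceptance bands are standard
binomial confidence intervals around the nominal rate, never tuned to a
particular draw.
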