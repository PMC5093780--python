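# Methods

`micronet` constructs and analyses co-abundance networks of microbial
*functional units* — groups of orthologous genes such as KEGG orthologous
groups (KOs) or eggNOG orthologous groups (OGs) — from shotgun metagenome
count data. This note documents the models, conventions and numerical
choices behind each stage, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Abundance profiling

The entry point is a gene x sample table of raw read counts with gene
lengths. The relative abundance of gene *i* in a sample is

    a_i = (x_i / l_i) / Σ_j (x_j / l_j)

with `x_i` the read count and `l_i` the gene length in bp: dividing by
length removes gene-length bias, and closing each sample to 1 removes
sequencing-depth differences. The abundance of functional unit *k* is the
plain sum `b_k = Σ_{j in S_k} a_j` over its annotated gene set `S_k`.
Conventions:

* A gene annotated to several units contributes its **full** abundance to
  each of them — the sum is not fractionated, and KO and OG namespaces are
  processed independently. Unit-level columns may therefore exceed 1 and
  are *not* re-normalised; downstream correlation is location/scale
  invariant per unit, so closure at the unit level would add nothing but
  would distort the sums.
* Before any network is built, the profile is restricted to the **common
  units**: those with strictly positive abundance in every sample. A unit
  absent from some samples cannot be correlated meaningfully across the
  cohort, and zero-variance vectors are rejected (not silently dropped) at
  the correlation stage precisely so that a skipped filter surfaces as an
  error rather than a wrong answer.
* Case/control sub-profiles are re-filtered independently after splitting,
  so each group's network is built on its own common units.

These profiles are *compositional*: each sample's gene-level abundances sum
to one by construction, which induces weak negative dependence among
unrelated units. The methods downstream are used on this closed scale, as
is standard in metagenome co-abundance analysis.

## Network inference

Given the N x n unit-by-sample matrix, both inference routes produce an
N x N association weight matrix, which is then sparsified.

**Pearson route.** Entry (i, j) is the Pearson correlation of the two
units' abundance vectors across samples. An optional permutation test
estimates the significance of each correlation: each replicate permutes the
sample order of one member of every pair (implemented as a single shared
permutation per replicate applied to the second member, which is equivalent
per pair and vectorises), recomputes r, and the two-sided empirical P value
counts replicates with `|r_perm| >= |r_obs|`, with add-one smoothing:
P = (k + 1)/(n_perm + 1), so P is never 0 and its floor is 1/(n_perm + 1).
The default replicate count is 10,000.

**Random-forest route.** The N-node network construction problem is cast as
N feature-selection subproblems: each unit in turn is the regression target
of a random forest grown on the remaining N − 1 units, and the importance of
predictor j for target i — impurity (variance) reduction attributed to j,
averaged across trees, *unnormalised* — is the directed weight j → i. Two
conventions matter:

* **Per-unit standardisation.** Every unit vector is standardised to zero
  mean and unit variance before fitting (the convention of GENIE3, the
  regulatory-network method this scheme mirrors). Without it, importances
  are in absolute variance units and the global edge ranking is dominated
  by high-variance units; with log-normally dispersed baselines this
  destroys recovery of planted structure.
* **Candidate features per split** default to sqrt(N − 1); the full
  (N − 1)-candidate variant and explicit counts are available. The default
  ensemble size is 1000 trees. Tests and the acceptance script run the
  500-unit standard fixture at 100 trees — at that problem size the
  importance ranking is already stable (planted-pair recovery ≥ 0.9), and
  the full matrix fits in about two minutes on one CPU.

The directed matrix is symmetrised before thresholding; the default rule
keeps the **max** of the two directed importances (the strongest evidence
for the association), with `mean` available.

**Thresholding.** The weighted complete graph is sparsified by the
*relative threshold* rule: keep the `floor(t·N)` highest-ranked pairs,
default t = 1.5 (capped at N(N−1)/2). Pearson edges are ranked by |r| with
the sign kept as an edge attribute — negative associations are evidence of
association too; RF edges by the symmetrised importance. Ties at the cutoff
are broken by lexicographic node-pair order so output is deterministic.
Units with no surviving edge are excluded from the node set. `floor` is the
package's fixed rounding convention for t·N. Alternatively a network can be
cut from permutation P values at a cutoff (default 0.01); `alpha = 1`
admits every pair.

## Topology panel

Reported per network: node and edge counts; density 2|E|/(n(n−1)); Freeman
degree centralization Σ(d_max − d_i)/((n−1)(n−2)); diameter and
characteristic path length on the **largest connected component**
(thresholded co-abundance networks are typically disconnected, and path
metrics are undefined across components); mean local clustering over nodes
of degree ≥ 2 (degree-1 nodes have no defined triangle fraction; averaging
over eligible nodes avoids an arbitrary 0-versus-excluded choice); and a
power-law fit to the degree distribution — ordinary least squares of
log10 P(k) on log10 k over raw (unbinned) observed degrees k ≥ 1, returning
the slope and R². Stress centrality counts, for each node v, the geodesics
between unordered pairs {s, t} on which v is interior; it is computed from
all-pairs BFS distance and geodesic-count matrices. Network intersection
keeps the edges present in both inputs and their endpoints, which restricts
downstream module detection to associations supported by both inference
methods.

## Dense-module detection

A re-implementation of the MCODE molecular-complex algorithm. Stage one
weights each vertex by its *core-clustering coefficient*: the density of
the highest k-core of the subgraph induced on its (open) neighborhood,
multiplied by that core's k. Stage two seeds complexes from the
highest-weight unvisited vertex (ties by node id, for reproducibility) and
grows them breadth-first over neighbors whose weight is within
`node_score_cutoff` (default 0.2) of the seed weight; a vertex joins at
most one complex. The haircut step trims each complex to its 2-core —
applied iteratively, so chains of singly-connected members are removed, not
just the outermost layer; if the trim severs a weak bridge the largest
connected piece is kept. The fluff step (off in the reference plugin's
defaults) is not implemented. A complex's score is the density of its
induced subgraph times its node count (so a clique of size k scores
k − 1 + … ≈ k), and modules scoring **strictly above 2.0** are retained by
the default filter. Degree cutoff 2 excludes leaves from seeding.

## Marker calling and group tests

A unit is a disease **marker** when a one-sided Wilcoxon rank-sum test of
case versus control abundance is significant at P < 1e-4 (no multiplicity
correction — the stringent fixed cutoff is the operating convention):
"enriched" when higher in cases, "depleted" when higher in controls. The
test uses the Mann-Whitney normal approximation with tie and continuity
corrections; an exact-enumeration oracle bounds its error in the test
suite for small groups.

Marker node groups are interrogated with two permutation nulls, both with
add-one smoothing (empirical P in (0, 1], never 0, reproducible by seed):

* **Edge-shuffle null** — each replicate rewires the network by
  10·|E| *accepted* double-edge swaps (swaps creating loops or duplicate
  edges are rejected; counting accepted swaps rather than attempts keeps
  replicates comparably mixed, attempts-counting is available), preserving
  every node's degree exactly, and recomputes the group's induced density.
  Tests whether a group is unusually densely interconnected given its
  degrees.
* **Node-label null** — replicates draw uniform random node sets of the
  group's size and recompute the statistic (group density, mean degree, or
  mean stress centrality), one-sided in either direction: marker groups can
  be tested both for unusually *low* degree and unusually *high* stress.

Per-module marker enrichment uses Pearson's chi-squared test (1 df, no
continuity correction) on the 2x2 table of in/out-of-module versus
marker/non-marker over the network's node set — the network, not the full
unit catalog, is the universe, because the question is where markers sit
*within* the network. Degenerate tables (no markers, or only markers) are
flagged rather than tested.

## Tetrad motif census and subgraph ratio profile

The six isomorphism classes of connected 4-node undirected graphs are
counted in the fixed order **path, star, cycle, paw, diamond, complete**
(the numbering "1–6" used in reports follows this order). Counting is
*induced*: each 4-node subset is classified once by the edges it induces.
Enumeration uses the ESU scheme (grow subgraphs from an anchor vertex via
exclusive neighbors with larger labels), which visits each connected subset
exactly once without scanning all C(n, 4) combinations — on sparse networks
this is what makes the census feasible. Classification needs only the
induced edge count and maximum degree.

The **subgraph ratio profile** compares the census against degree-matched
random networks (default 100 replicates, each rewired with 10·|E| accepted
swaps — the same mixing budget as the enrichment null, for consistency):

    Δ_i = (N_real_i − ⟨N_rand_i⟩) / (N_real_i + ⟨N_rand_i⟩ + 4)

where ⟨·⟩ is the null mean; the +4 damps classes rare in both. The Δ vector
normalised to unit Euclidean length is a size-independent signature of
local structure. If every Δ is zero the normalised vector is reported as
zero with a degenerate flag. Correlation-based networks characteristically
over-represent the dense tetrads (diamond, complete) relative to their
degree-matched nulls, because correlation is transitive enough to close
triangles; this is reproduced on the synthetic fixture.

## Module-feature classifier

Each detected module yields one feature per sample: the arithmetic mean of
its member units' abundances. Classification is logistic regression under
stratified k-fold cross-validation (default k = 10), with features
standardised inside each fold by training-fold statistics. The fit is
unpenalised; if it fails to converge (quasi-separation on a small fold) a
weak ridge (C = 1e3) is substituted so the pipeline cannot crash on
separable folds. Out-of-fold predicted probabilities are pooled — one
prediction per sample — and a single ROC/PR pair is computed from the pool
(pooling, rather than averaging per-fold curves, is the stable convention
at a few hundred samples). AUC is the trapezoid-rule area, identical to
the normalised Mann-Whitney statistic with ties counted half; AUPR is the
step-wise (average-precision) integral, with the zero-prediction endpoint
taken as (recall 0, precision 1).

## Synthetic fixtures

The generator plants known structure so every stage is testable without
external data. Log abundance of unit u in sample s is

    log b_us = baseline_u + loading · f_{m(u), s} + shift_u · group_s + σ ε

with unit baselines ~ N(0, 1) (log-scale dispersion between units),
one latent factor f per planted module drawn per sample (loading 0.8 by
default, giving within-module correlation ≈ loading²/(loading² + σ²) ≈ 0.7
at σ = 0.5), a case/control shift for marker units expressed in units of
the per-sample noise SD, and N(0, σ²) noise. Columns are exponentiated and
closed to 1, so the methods face the same compositional constraint as real
profiles. A gene-level table can be emitted by splitting each unit over a
few genes with Dirichlet proportions, drawing lengths uniformly in
0.3–3 kb, and inverting the length normalisation at a configured depth
(counts rounded to integers), so the profiling path is exercised end to
end up to quantisation error.

The **standard fixture** is 500 units, 100 case + 100 control samples,
three planted modules of sizes 8/10/12 at loading 0.8, and 30 markers
(15 enriched, 15 depleted) at a 1.5-SD shift, seed-determined throughout.
Markers and modules are disjoint there, so module features are
uninformative about the group label by design; module specs can instead
carry their own group effect when a discriminative-module condition is
wanted.

What the generator does **not** emulate: taxonomic structure and
phylogenetic correlation, read-level error, over-dispersed zero-inflated
counts, unequal sequencing depth artefacts beyond closure, and annotation
incompleteness. Passing recovery tests therefore demonstrates correctness
of the algorithms under the assumed latent-factor/log-normal model, not
performance on real metagenomes.

## Problem sizes and determinism

The test suite and the acceptance script run the standard fixture with a
100-tree RF ensemble, 50–100 motif randomizations, and permutation nulls at
10²–10³ replicates; these are the package's chosen desk-scale problem
sizes, and every such knob is a parameter with the study-scale value
(1000 trees, 10,000 replicates, 100 randomizations) as the library
default. All randomness flows through named integer seeds
(`numpy.random.default_rng` / `SeedSequence`); no global RNG state is
touched, and a pipeline rerun with the same configuration is byte-identical
including the JSON report (which records every threshold and seed used).

## Known limitations

* Pearson correlation on closed (compositional) data is biased negative for
  unrelated units; compositionality-aware measures are out of scope.
* The RF importance matrix is quadratic-in-N work (N forests); very large
  unit catalogs need the relative threshold route on PCC or subsampling.
* The MCODE re-implementation follows the published two-stage algorithm
  with the plugin's documented defaults, but plugin-version idiosyncrasies
  are not reproduced bug-for-bug.
* The permutation P floor 1/(n + 1) bounds attainable significance; claims
  below that floor require more replicates.
* Stress centrality is exact but O(n·m + n³) in its accumulation step;
  fine for thousands of nodes, not for millions.
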