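# micronet

Functional-unit co-abundance networks for shotgun metagenomes.

A microbial community carries millions of genes — far too many to network
directly. `micronet` follows the functional-network strategy: map genes to
**functional units** (KEGG orthologous groups, KOs, or eggNOG orthologous
groups, OGs), profile each unit's relative abundance across samples, and
build a network whose nodes are units and whose edges are strong
co-abundance associations. The package is for microbiome researchers who
have a gene x sample count table (plus gene lengths and a gene→KO/OG map)
and want the full downstream analysis: network inference by two routes,
topology panels, dense functional modules, case/control markers with
permutation tests, local-structure (motif) signatures, and a module-based
classifier.

## The model in brief

**Profiling.** Gene relative abundance is length-normalised and closed per
sample, `a_i = (x_i/l_i) / Σ_j (x_j/l_j)`; unit abundance is the sum over
the unit's gene set, `b_k = Σ_{j∈S_k} a_j`. Only units with nonzero
abundance in every sample enter network construction.

**Inference.** Two routes produce an N x N weight matrix over units:

* *PCC* — Pearson's correlation `r` of the two units' abundance vectors
  across samples, with an optional 10,000-replicate permutation P value;
* *RF* — each unit in turn is the target of a random-forest regression on
  the remaining N−1 units (N feature-selection subproblems, as in GENIE3);
  the importance of predictor j for target i (variance reduction averaged
  over trees) weights the association j→i, and the directed matrix is
  symmetrised by max.

The network keeps the `floor(1.5 N)` highest-ranked pairs (the *relative
threshold* 1.5; |r| for PCC, importance for RF).

**Analysis.** Topology panel (density, Freeman centralization, diameter,
clustering, power-law degree fit, stress centrality); intersection of the
two networks; MCODE-style dense modules kept at score > 2.0; one-sided
Wilcoxon case/control markers at P < 1e-4; degree-preserving edge-shuffle
and node-label permutation nulls for marker groups; Pearson χ² module
enrichment; the six-class connected-tetrad census with the subgraph ratio
profile `Δ_i = (N_real−⟨N_rand⟩)/(N_real+⟨N_rand⟩+4)` against 100
degree-matched random networks; and a 10-fold cross-validated logistic
classifier on module-mean abundance features (pooled AUC / AUPR).

A seeded synthetic-fixture generator plants co-abundance modules (shared
latent factors) and differential markers in log-normal, compositionally
closed profiles, so the whole stack is testable without any external data.

## Worked example

```python
import micronet as mn

cfg = mn.SynthConfig(
    n_units=150, n_case=50, n_control=50,
    modules=[mn.ModuleSpec(8), mn.ModuleSpec(10)], seed=2,
)
profile, truth = mn.generate_profile(cfg)

net_pcc = mn.threshold_network(mn.pcc_weight_matrix(profile), 1.5)
net_rf = mn.threshold_network(
    mn.symmetrize(mn.rf_weight_matrix(profile, n_trees=100, seed=3)), 1.5
)
for name, net in (("PCC", net_pcc), ("RF", net_rf)):
    s = mn.topology_summary(net, fit_degrees=False)
    rec = sum(net.has_edge(*tuple(p)) for p in truth.true_pairs()) / len(truth.true_pairs())
    print(name, s.n_nodes, s.n_edges, f"{s.density:.3f}", f"{rec:.0%}")
```

prints

```
PCC 129 225 0.027 100%
RF 131 225 0.026 97%
```

— both methods keep the same edge budget (floor(1.5·150) = 225), and both
place essentially all 73 planted within-module pairs among those edges;
PCC concentrates edges on fewer nodes than RF, as expected from a
correlation-based ranking. Running the motif profile on the PCC network
(`examples/04_motif_profile.py`) shows the characteristic correlation
signature — dense tetrads far above degree-matched chance:

```
class         real   null mean    delta  normalized
path          1165      4533.3   -0.591      -0.370
...
diamond        257        73.7    0.547       0.343
complete       313         3.0    0.969       0.607
```

The `examples/` directory has one short script per capability: profiling
from gene counts, network inference, modules + markers + enrichment, the
motif profile, and the module classifier. A thin CLI mirrors the library
(`micronet simulate | profile | network | topology | modules | markers |
enrich | motifs | classify | run`); `micronet run` executes the whole
pipeline and writes every artifact plus a seed-deterministic
`report.json`.

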