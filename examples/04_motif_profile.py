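"""Tetrad motif census and the subgraph ratio profile.

Counts the six connected 4-node subgraph classes in a PCC network and
compares them with degree-matched random networks: the subgraph ratio
profile (SRP) is the unit-length vector of per-class scores
delta = (real - null) / (real + null + 4).
"""

import micronet as mn

cfg = mn.SynthConfig(
    n_units=120, n_case=60, n_control=60,
    modules=[mn.ModuleSpec(8), mn.ModuleSpec(10)], seed=8,
)
profile, _ = mn.generate_profile(cfg)
net = mn.threshold_network(mn.pcc_weight_matrix(profile), 1.5)

srp = mn.subgraph_ratio_profile(net, n_random=50, seed=9)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
print(f"{'class':<10}{'real':>8}{'null mean':>12}{'delta':>9}{'normalized':>12}")
for cls, real, null, d, z in zip(
    mn.TETRAD_CLASSES, srp.real_counts, srp.null_means, srp.delta, srp.normalized
):
    print(f"{cls:<10}{real:>8d}{null:>12.1f}{d:>9.3f}{z:>12.3f}")
# Positive delta for the dense classes (diamond, complete) says the
# correlation network closes triangles far more often than degree-matched
# chance — the characteristic local signature of PCC-based networks.
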