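"""Classify case vs control samples from module-mean abundance features.

Plants two modules whose member units are shifted between cases and
controls, builds one feature per module (mean member abundance per
sample), and evaluates a logistic regression with stratified 10-fold
cross-validation, reporting pooled AUC and AUPR.
"""

import micronet as mn

cfg = mn.SynthConfig(
    n_units=200, n_case=100, n_control=100,
    modules=[
        mn.ModuleSpec(8, effect=4.0, direction="enriched"),
        mn.ModuleSpec(10, effect=4.0, direction="depleted"),
    ],
    seed=10,
)
profile, truth = mn.generate_profile(cfg)

modules = mn.ModuleSet(modules=[
    mn.Module(frozenset(truth.module_members(i)), score=3.0, rank=i + 1)
    for i in range(truth.n_modules())
])
features = mn.module_features(profile, modules)
cv = mn.crossval_logistic(features, k=10, seed=11)
curves = mn.roc_pr(cv)

print(f"feature matrix: {features.values.shape[0]} samples x "
      f"{features.values.shape[1]} module features")
print(f"pooled 10-fold AUC  = {curves['auc']:.3f}")
print(f"pooled 10-fold AUPR = {curves['aupr']:.3f}")
# AUC near 1 means the module-mean features separate the groups almost
# perfectly; with no planted effect the same pipeline hovers near 0.5.
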