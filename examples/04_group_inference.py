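"""Covariate-adjusted permutation inference on planted group effects.

Plants the insomnia-pattern disruption (local efficiency up, global
efficiency down in the IS group) into synthetic connectomes, summarises
each metric by its AUC over the sparsity grid, and tests the group
difference with a Freedman–Lane permutation test adjusting for gender,
age, education and the adjusted anxiety/depression scores.
"""

import numpy as np

import wmnet as w

table = w.generate_cohort(w.CohortSpec(seed=3))
effects = w.EffectSpec.insomnia_default()
conns = w.generate_connectomes(table, n_nodes=90, effects=effects, seed=4)

auc = {"Eglo": [], "Eloc": []}
for sid in table["id"]:
    curves = w.metric_curves(conns[sid], include_nodal=False, include_small_world=False)
    for m in auc:
        auc[m].append(float(curves[m].auc))

covs = w.covariate_matrix(table)
is1 = (table["group"] == "IS").to_numpy()
print(f"{'metric':>6} {'t':>8} {'p':>8}  direction")
for m, vals in auc.items():
    res = w.permutation_group_test(
        np.array(vals), is1, n_perm=4999, seed=5, covariates=covs
    )
    arrow = "IS higher" if res.direction > 0 else "IS lower"
    print(f"{m:>6} {res.statistic:>8.3f} {res.p:>8.4f}  {arrow}")
print()
print(
    "The planted pattern is recovered: global efficiency is lower and\n"
    "local efficiency higher in the IS group, the shift toward a more\n"
    "regular (lattice-like) topology that the generator encodes."
)
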