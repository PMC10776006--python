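"""Association statistics: weighted correlations, permutation tests,
cross-validated receptor GLMs and receptor-set PCA.

Builds a synthetic study with planted receptor relationships (GABA-like and
5-HT1A-like maps tied with opposite signs to the activation ratio b/d;
5-HT1B-like and 5-HT2A-like maps tied to the normalization constant d) and
runs the full statistical battery at ROI level.
"""

import numpy as np

from dnprf import (
    crossval_glm,
    group_parameter_map,
    pca_receptors,
    permutation_test,
    roi_summaries,
    surrogate_pair_test,
)
from dnprf.synth import TruthSpec, make_truth, simulate_participant_estimates, simulate_receptors

truth = make_truth(TruthSpec(seed=11))
receptors = simulate_receptors(truth, seed=12)  # planted |wCC| = 0.65
fits = simulate_participant_estimates(truth, n_participants=40, seed=13)

roi = roi_summaries(group_parameter_map(fits), truth.roi.to_numpy(), receptors)
t, w = roi.table, roi.weights

print("one-dimensional weighted correlations (planted signs +, -, +, -):")
for param, receptor in [("bd", "GABA"), ("bd", "5HT1A"), ("d", "5HT1B"), ("d", "5HT2A")]:
    res = permutation_test(t[receptor], t[param], w, n_perm=100_000, seed=1)
    print(f"  {param:2s} ~ {receptor:6s}: {res}")

# split-half cross-validated GLMs: two receptors beat either alone
half_a = simulate_participant_estimates(truth, 20, seed=21)
half_b = simulate_participant_estimates(truth, 20, seed=22)
roi_a = roi_summaries(group_parameter_map(half_a), truth.roi.to_numpy(), receptors)
roi_b = roi_summaries(group_parameter_map(half_b), truth.roi.to_numpy(), receptors)
ya, yb = roi_a.table["bd"].to_numpy(), roi_b.table["bd"].to_numpy()
Xa = roi_a.table[["GABA", "5HT1A"]].to_numpy()
Xb = roi_b.table[["GABA", "5HT1A"]].to_numpy()
print("\ncross-validated wCC(cv) for the activation ratio:")
print(f"  GABA + 5HT1A : {crossval_glm(Xa, ya, roi_a.weights, Xb, yb, roi_b.weights):.2f}")
print(f"  GABA alone   : {crossval_glm(Xa[:, 0], ya, roi_a.weights, Xb[:, 0], yb, roi_b.weights):.2f}")
print(f"  5HT1A alone  : {crossval_glm(Xa[:, 1], ya, roi_a.weights, Xb[:, 1], yb, roi_b.weights):.2f}")

surro = surrogate_pair_test(t["GABA"], t["5HT1A"], t["bd"], w,
                            n_perm=10_000, seed=2, names=("GABA", "5HT1A"))
print(f"  surrogate-receptor p: GABA {surro.p['GABA']:.4f}, "
      f"5HT1A {surro.p['5HT1A']:.4f}")

pca = pca_receptors(t[roi.receptor_columns])
print(f"\nreceptor PCA variance ratios: {np.round(pca.variance_ratio, 3)}")
print(f"components above the 1/{len(roi.receptor_columns)} equivariance "
      f"threshold: {pca.n_above_threshold}")
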