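"""Model a single gene link and score its classification power.

Fits the two-node Markov chain (initial distribution of the source
gene + 3x3 state transition matrix) for each class and reports the
link's leave-one-out classification accuracy d — the probability that
a held-out sample is assigned to its true class by comparing the joint
likelihoods P0(x) * M[x, y] under the two class models.
"""

import numpy as np

from dynsig import (SimulationConfig, discretize_matrix, fit_mcmlink,
                    link_permutation_pvalue, loocv_link_score,
                    simulate_dataset)

ds = simulate_dataset(SimulationConfig(n_pathways=4, n_per_class=30,
                                       r=0.7, rho=1.0, seed=11))
states = discretize_matrix(ds.expression, "fixed", thresholds=(2, 4))

src, dst = ds.pathways[0].links[0]          # first link of a true DEP
s1 = states.states[states.gene_row(src)]
s2 = states.states[states.gene_row(dst)]

for cls in states.classes:
    mask = states.class_mask(cls)
    model = fit_mcmlink(s1[mask], s2[mask], link=(src, dst))
    print(f"{cls}: P0 = {np.round(model.P0, 2)}")
    print(f"   TPM =\n{np.round(model.M, 2)}")

a, d = loocv_link_score(s1, s2, states.labels)
p = link_permutation_pvalue(s1, s2, states.labels, B=200, rng=0)
print(f"\nlink {src} -> {dst}: LOOCV accuracy d = {d:.3f} "
      f"({int(a.sum())}/{a.size} samples correct), permutation p = {p:.3f}")
print("d near 1 means the link's signaling dynamics separate the classes;"
      "\nd near 0.5 means it classifies no better than chance.")
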