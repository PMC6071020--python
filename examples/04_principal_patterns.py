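"""Extract class-specific principal signaling patterns along a cascade.

For each class, fits a Markov chain model per link and works backward
from the ending link, picking the most probable state-transition mode
at each step. In a differential pathway the two classes show different
patterns; the simulation's generating major states are printed for
comparison.
"""

import numpy as np

from dynsig import (GeneChain, SimulationConfig, principal_pattern,
                    simulate_dataset)

ds = simulate_dataset(SimulationConfig(n_pathways=10, n_per_class=60,
                                       r=0.8, rho=1.0, seed=5))
names = np.array(["D", "N", "U"])

pw = ds.pathways[0]                        # a true DEP
chain = GeneChain([f"{pw.name}_g{i:02d}" for i in range(1, 11)])
print(f"chain: {' -> '.join(g.split('_')[1] for g in chain.genes)}")
for c, cls in enumerate(("control", "case")):
    pat = principal_pattern(chain, ds.states, cls)
    want = " -> ".join(names[ds.major_states[c, :10]])
    print(f"{cls:>8}: {pat}   (generating: {want})")
print("\nDistinct patterns between classes are the signature of a"
      "\ndifferentially expressed pathway; matching patterns would mean"
      "\nthe pathway's signaling flow is preserved across conditions.")
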