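"""Generate a two-class benchmark dataset with known pathway truth.

Builds 20 ten-gene cascade pathways (half truly differential), 30
samples per class, with the dominant-pattern probability r = 0.6 and
half of each differential pathway's genes changing their major
regulatory state between classes.
"""

import numpy as np

from dynsig import SimulationConfig, simulate_dataset

cfg = SimulationConfig(structure="cascade", n_pathways=20, n_per_class=30,
                       r=0.6, rho=0.5, seed=7)
ds = simulate_dataset(cfg)

print(f"expression matrix: {ds.expression.values.shape[0]} genes x "
      f"{ds.expression.values.shape[1]} samples, classes {ds.expression.classes}")
print(f"pathways: {len(ds.pathways)} ({int(ds.dep_truth.sum())} true DEPs), "
      f"{int(ds.deg_truth.sum())} true DEGs")

# a gene keeps its major state in ~r of the samples
freq = (ds.states.states[:, :30] == ds.major_states[0][:, None]).mean()
print(f"empirical major-state frequency: {freq:.3f} (target r = {cfg.r})")

# first DEP: which genes changed state between classes?
names = np.array(["D", "N", "U"])
print("pathway", ds.pathways[0].name, "majors:")
print("  control:", " ".join(names[ds.major_states[0, :10]]))
print("  case:   ", " ".join(names[ds.major_states[1, :10]]))
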