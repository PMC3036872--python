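"""AMOVA and pairwise Phi_ST on Tamura-Nei distances."""

import numpy as np

from mtpopgen import DistanceModelParams, amova, distance_matrix, pairwise_phist
from mtpopgen.sim import SimConfig, simulate_dataset

# five localities painted on one panmictic expansion genealogy: the regime
# in which no genuine structure exists
out = simulate_dataset(SimConfig(scenario="sudden_expansion", n=[17, 21, 17, 18, 20],
                                 L=993, theta0=0.03, theta1=62.6, tau=8.1, seed=3))
params = DistanceModelParams("TN93+G", alpha=0.61)
d = distance_matrix(out.alignment, params)
labels = [out.popmap.of(s) for s in out.alignment.ids]

res = amova(d**2, labels, n_perms=1000, seed=1)
print(f"Phi_ST = {res.phi_st:.5f} (p = {res.p_value:.3f})")
print("percent of variation:", {k: round(v, 2) for k, v in res.percent.items()})

groups = {"pop0": "north", "pop1": "north", "pop2": "north", "pop3": "south", "pop4": "south"}
res2 = amova(d**2, labels, groups=groups, n_perms=500, seed=2)
print(f"two-level: Phi_CT = {res2.phi_ct:.5f} (p = {res2.p_ct:.3f})")

pw = pairwise_phist(d**2, labels, n_perms=200, seed=3)
print("pairwise Phi_ST (lower triangle):")
print(pw.phi_st.round(4).fillna(""))
# values scattered around zero with large p-values mean the localities are
# samples from one panmictic population.
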