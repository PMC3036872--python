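"""Haplotype table, sharing summary and diversity indices.

Uses the bundled Chinese-shrimp control-region haplotype counts for the
count-based statistics, and a small simulated alignment for the
sequence-based ones.
"""

from mtpopgen import collapse_haplotypes, haplotype_diversity, nucleotide_diversity
from mtpopgen.alignio import HaplotypeTable, shared_private_summary
from mtpopgen.datasets import load_fchinensis_counts
from mtpopgen.sim import SimConfig, simulate_dataset

counts = load_fchinensis_counts()
tbl = HaplotypeTable(tuple(f"SEQ{i}" for i in counts.index), counts)
n_shared, n_private, pct = shared_private_summary(tbl)
print(f"haplotypes: {tbl.k} in {tbl.n} individuals")
print(f"shared among localities: {n_shared}; locality-specific: {n_private} ({pct} %)")

for pop in counts.columns:
    col = counts[pop]
    col = col[col > 0]
    h, sd = haplotype_diversity(col.to_numpy())
    print(f"{pop}: n={int(col.sum())}, K={len(col)}, h = {h:.4f} +- {sd:.4f}")
# h is the probability that two random individuals carry different haplotypes.

out = simulate_dataset(SimConfig(scenario="sudden_expansion", n=20, L=993,
                                 theta0=0.03, theta1=62.6, tau=8.1, seed=4))
pi, sd_pi = nucleotide_diversity(out.alignment)
tbl2 = collapse_haplotypes(out.alignment, out.popmap)
print(f"simulated expansion sample: K={tbl2.k}, pi = {100 * pi:.3f} % +- {100 * sd_pi:.3f} %")
# an expansion regime gives many haplotypes but modest per-site diversity.
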