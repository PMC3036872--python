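"""Minimum spanning network of haplotypes."""

from mtpopgen import collapse_haplotypes, minimum_spanning_network, pairwise_differences
from mtpopgen.alignio import Alignment
from mtpopgen.network import network_to_dataframe
from mtpopgen.sim import SimConfig, simulate_dataset

out = simulate_dataset(SimConfig(scenario="sudden_expansion", n=30, L=993,
                                 theta0=0.001, theta1=150.0, tau=4.0, seed=8))
tbl = collapse_haplotypes(out.alignment, out.popmap)
hap_aln = Alignment(tuple(f"h{i}" for i in tbl.counts.index), tbl.sequences)
diffs, _ = pairwise_differences(hap_aln)
edges = minimum_spanning_network(tbl, diffs)

df = network_to_dataframe(edges)
print(df.to_string(index=False))
n_alt = int(df["alternative"].sum())
print(f"\n{tbl.k} haplotypes, {int(df['in_mst'].sum())} tree edges, {n_alt} alternative edges")
# edge weights are raw substitution counts; under a recent expansion the
# network is star-like, with a frequent central haplotype.
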