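"""Tajima's D and Fu's Fs with coalescent p-values.

The pooled survey statistics (n=93 sequences, S=84 segregating sites, K=68
haplotypes, mean pairwise difference = pi * 993 sites) are enough to evaluate
both statistics; p-values come from neutral coalescent replicates.
"""

from mtpopgen import fus_Fs, neutrality_pvalues, tajimas_D

n, S, K = 93, 84, 68
k_mean = 0.7598 / 100 * 993  # mean pairwise differences from pi

D = tajimas_D(n, S, k_mean)
Fs = fus_Fs(n, K, k_mean)
print(f"Tajima's D = {D:.2f}   Fu's Fs = {Fs:.2f}")

res = neutrality_pvalues(n, S, k_mean, K, n_reps=1000, seed=1)
print(f"p(D)  = {res.p_D:.3f}   p(Fs) = {res.p_Fs:.3f}")
# Strongly negative D and Fs with small p-values are the classic signature
# of recent population expansion (excess of rare variants and haplotypes).
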