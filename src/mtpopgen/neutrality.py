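"""Tajima's D and Fu's Fs with coalescent-simulation p-values.

Both statistics contrast different summaries of polymorphism that estimate
the same scaled mutation rate under neutral equilibrium.  Tajima's D compares
the mean number of pairwise differences with the Watterson estimate from the
number of segregating sites; Fu's Fs asks how improbable the observed number
of distinct haplotypes K is under the Ewens sampling formula when theta is
estimated from the mean pairwise differences.  Strongly negative values of
either — an excess of rare variants or of rare haplotypes — are the classic
signature of recent population expansion, which is the direction the
one-sided p-values test.

p-values come from neutral constant-size coalescent replicates conditioned on
the observed number of segregating sites (mutations placed multinomially on
branches), the convention of the standard tools for these tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from . import sim as _sim

__all__ = [
    "NeutralityResult",
    "tajimas_D",
    "fus_Fs",
    "log_stirling_first_kind",
    "ewens_log_pmf",
    "neutrality_pvalues",
    "simulate_null_statistics",
]


@dataclass
class NeutralityResult:
    D: float
    p_D: float
    Fs: float
    p_Fs: float
    n: int
    S: int
    k_mean: float
    K: int
    n_reps: int

    def __post_init__(self) -> None:
        for p in (self.p_D, self.p_Fs):
            if not (np.isnan(p) or 0.0 <= p <= 1.0):
                raise ValueError("p-values must lie in [0, 1]")


def tajimas_D(n: int, S: int, k_mean: float) -> float:
    """Tajima's (1989) D from sample size, segregating sites and mean
    pairwise differences.  Returns NaN when S = 0 (statistic undefined)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((k_mean - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))


@lru_cache(maxsize=32)
def log_stirling_first_kind(n: int) -> np.ndarray:
    """log |S1(n, k)| for k = 0..n (unsigned Stirling numbers, 1st kind).

    Built in log space from the recurrence
    |S1(m, k)| = (m-1) |S1(m-1, k)| + |S1(m-1, k-1)|.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0
    for m in range(1, n + 1):
        shifted = np.concatenate(([-np.inf], row[:-1]))
        if m > 1:
            row = np.logaddexp(np.log(m - 1) + row, shifted)
        else:
            row = shifted
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k) for k = 0..n under the Ewens sampling formula:
    Pr(K=k) = |S1(n,k)| theta^k / theta^(n), theta^(n) rising factorial."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    k = np.arange(n + 1)
    log_rising = gammaln(theta + n) - gammaln(theta)
    return log_stirling_first_kind(n) + k * np.log(theta) - log_rising


def fus_Fs(n: int, K: int, k_mean: float) -> float:
    """Fu's (1997) Fs.

    With theta estimated by the mean pairwise differences, S' is the Ewens
    probability of observing at least K haplotypes in a sample of n, and
    Fs = ln(S'/(1 - S')).  K = 1 or theta = 0 makes S' = 1 and Fs = +inf.
    """
    if not (2 <= n and 1 <= K <= n):
        raise ValueError("need n >= 2 and 1 <= K <= n")
    if K == 1 or k_mean <= 0:
        return float("inf")
    logp = ewens_log_pmf(n, k_mean)
    log_Sp = logsumexp(logp[K:])
    if log_Sp >= 0.0:
        return float("inf")
    # ln(S'/(1-S')) computed stably for tiny S'
    return float(log_Sp - np.log1p(-np.exp(log_Sp)))


def simulate_null_statistics(
    n: int, S: int, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions of (D, Fs) from neutral constant-size coalescent
    genealogies with exactly S mutations placed by branch length."""
    config = _sim.SimConfig(scenario="constant", n=n, theta=1.0)
    D = np.empty(n_reps)
    Fs = np.empty(n_reps)
    pair_norm = n * (n - 1) / 2.0
    for r in range(n_reps):
        tree = _sim.simulate_genealogy(config, rng)
        muts = _sim.branch_mutation_counts(tree, rng, total=S)
        # mean pairwise differences via subtended-tip counts
        sizes = _tip_counts(tree)
        k_mean = float(
            (muts * sizes * (n - sizes)).sum() / pair_norm
        )
        K = _sim.count_haplotypes_from_mutations(tree, muts)
        D[r] = tajimas_D(n, S, k_mean)
        Fs[r] = fus_Fs(n, K, k_mean) if k_mean > 0 else np.inf
    return D, Fs


def _tip_counts(tree: "_sim.SimTree") -> np.ndarray:
    sizes = np.zeros(tree.n_nodes, dtype=int)
    sizes[: tree.n_tips] = 1
    for v in np.argsort(tree.time):
        p = tree.parent[v]
        if p >= 0:
            sizes[p] += sizes[v]
    return sizes


def neutrality_pvalues(
    n: int,
    S: int,
    k_mean: float,
    K: int,
    n_reps: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """Observed D and Fs with one-sided (negative-tail) simulation p-values.

    p is the fraction of neutral replicates with a statistic <= the observed
    value, the direction in which population expansion pulls both statistics.
    """
    if n_reps < 100:
        raise ValueError("use at least 100 replicates for p-values")
    rng = np.random.default_rng(seed)
    D_obs = tajimas_D(n, S, k_mean)
    Fs_obs = fus_Fs(n, K, k_mean)
    D_sim, Fs_sim = simulate_null_statistics(n, S, n_reps, rng)
    p_D = float(np.mean(D_sim <= D_obs))
    p_Fs = float(np.mean(Fs_sim <= Fs_obs))
    return NeutralityResult(D_obs, p_D, Fs_obs, p_Fs, n, S, k_mean, K, n_reps)
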