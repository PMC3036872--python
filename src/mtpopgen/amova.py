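"""Analysis of molecular variance (AMOVA) and pairwise Phi_ST.

AMOVA partitions the total molecular variance, defined through squared
pairwise distances between individuals, into hierarchical components
(Excoffier, Smouse & Quattro 1992).  Sums of squares are computed directly
from the squared-distance matrix:

    SS_total  = sum_{i<j} d2_ij / n
    SS_within = sum_pop sum_{i<j in pop} d2_ij / n_pop

and variance components follow from the expected mean squares with the
standard unequal-sample-size coefficients.  Phi statistics are ratios of
components; their significance comes from permuting individuals among
populations (and whole populations among groups for Phi_CT).  Components can
legitimately be negative (sampling noise around zero differentiation) and
are reported as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["AmovaResult", "PairwiseFstMatrix", "amova", "pairwise_phist"]


@dataclass
class AmovaResult:
    df: dict[str, int]
    ss: dict[str, float]
    sigma2: dict[str, float]
    percent: dict[str, float]
    phi_st: float | None
    p_value: float
    n_perms: int
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_ct: float | None = None
    p_sc: float | None = None
    defined: bool = True

    def table(self) -> pd.DataFrame:
        rows = [
            {"stratum": k, "df": self.df.get(k), "SS": self.ss.get(k),
             "sigma2": self.sigma2.get(k), "percent": self.percent.get(k)}
            for k in self.df
        ]
        return pd.DataFrame(rows)


@dataclass
class PairwiseFstMatrix:
    populations: list[str]
    phi_st: pd.DataFrame
    p_values: pd.DataFrame
    n_perms: int


def _check_inputs(d2: np.ndarray, labels: list[str]) -> None:
    d2 = np.asarray(d2)
    if d2.ndim != 2 or d2.shape[0] != d2.shape[1]:
        raise ValueError("squared-distance matrix must be square")
    if len(labels) != d2.shape[0]:
        raise ValueError("one population label per individual required")


def _ss_within(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in parts:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / 2.0 / len(idx)
    return ss


def _one_level_components(d2: np.ndarray, labels: np.ndarray, pops: list):
    n = d2.shape[0]
    parts = [np.flatnonzero(labels == p) for p in pops]
    sizes = np.array([len(ix) for ix in parts], dtype=float)
    P = len(pops)
    ss_total = d2.sum() / 2.0 / n
    ss_within = _ss_within(d2, parts)
    ss_among = ss_total - ss_within
    df_among, df_within = P - 1, n - P
    sigma_w = ss_within / df_within if df_within > 0 else 0.0
    n_prime = (n - (sizes**2).sum() / n) / (P - 1)
    ms_among = ss_among / df_among
    sigma_a = (ms_among - sigma_w) / n_prime
    return ss_total, ss_among, ss_within, df_among, df_within, sigma_a, sigma_w


def _phi(sigma_a: float, sigma_w: float) -> float | None:
    total = sigma_a + sigma_w
    if total == 0.0:
        return None
    return sigma_a / total


def _two_level_components(d2, labels, pops, group_of):
    n = d2.shape[0]
    P = len(pops)
    groups = list(dict.fromkeys(group_of[p] for p in pops))
    G = len(groups)
    pop_parts = {p: np.flatnonzero(labels == p) for p in pops}
    grp_parts = {
        g: np.concatenate([pop_parts[p] for p in pops if group_of[p] == g]) for g in groups
    }
    sizes = {p: len(pop_parts[p]) for p in pops}
    gsizes = {g: len(grp_parts[g]) for g in groups}

    ss_total = d2.sum() / 2.0 / n
    ss_wp = _ss_within(d2, list(pop_parts.values()))
    ss_wg = _ss_within(d2, list(grp_parts.values()))
    ss_ap = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_total - ss_wg       # among groups

    df_wp, df_ap, df_ag = n - P, P - G, G - 1
    sigma_c = ss_wp / df_wp if df_wp else 0.0
    sum_nsq_by_group = {
        g: sum(sizes[p] ** 2 for p in pops if group_of[p] == g) for g in groups
    }
    n1 = (n - sum(sum_nsq_by_group[g] / gsizes[g] for g in groups)) / df_ap
    n2 = (
        sum(sum_nsq_by_group[g] / gsizes[g] for g in groups)
        - sum(sizes[p] ** 2 for p in pops) / n
    ) / df_ag
    n3 = (n - sum(gsizes[g] ** 2 for g in groups) / n) / df_ag
    sigma_b = (ss_ap / df_ap - sigma_c) / n1
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return {
        "ss": {"among_groups": ss_ag, "among_populations": ss_ap, "within_populations": ss_wp,
               "total": ss_total},
        "df": {"among_groups": df_ag, "among_populations": df_ap, "within_populations": df_wp},
        "sigma": (sigma_a, sigma_b, sigma_c),
    }


def amova(
    dist_matrix_squared: np.ndarray,
    labels: list[str],
    groups: dict[str, str] | None = None,
    n_perms: int | str = 5000,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA over a squared-distance matrix and per-individual labels.

    ``groups`` optionally maps each population to a higher-level group,
    turning the analysis into a two-level one (among groups / among
    populations within groups / within populations).  ``n_perms`` may be
    ``"exhaustive"`` to enumerate every reassignment of individuals to
    populations of the observed sizes (small samples only).
    """
    d2 = np.asarray(dist_matrix_squared, dtype=float)
    labels = np.asarray(labels)
    _check_inputs(d2, list(labels))
    pops = list(dict.fromkeys(labels.tolist()))
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    rng = np.random.default_rng(seed)

    if groups is not None:
        missing = set(pops) - set(groups)
        if missing:
            raise ValueError(f"groups must cover all populations; missing {sorted(missing)}")
        n_groups = len(set(groups[p] for p in pops))
        if len(pops) <= n_groups:
            raise ValueError("two-level AMOVA needs more populations than groups")
        return _amova_two_level(d2, labels, pops, groups, n_perms, rng)

    ss_total, ss_among, ss_within, df_a, df_w, sigma_a, sigma_w = _one_level_components(
        d2, labels, pops
    )
    phi = _phi(sigma_a, sigma_w)
    total_var = sigma_a + sigma_w
    if phi is None:
        warnings.warn("zero total variance: Phi_ST undefined")
        pct = {"among_populations": 0.0, "within_populations": 0.0}
        return AmovaResult(
            {"among_populations": df_a, "within_populations": df_w, "total": df_a + df_w},
            {"among_populations": ss_among, "within_populations": ss_within, "total": ss_total},
            {"among_populations": sigma_a, "within_populations": sigma_w},
            pct, None, float("nan"), 0, defined=False,
        )

    def stat(perm_labels):
        *_, sa, sw = _one_level_components(d2, perm_labels, pops)
        tot = sa + sw
        return sa / tot if tot != 0 else -np.inf

    if n_perms == "exhaustive":
        perms = _distinct_assignments(labels)
        count = sum(1 for pl in perms if stat(pl) >= phi - 1e-12)
        n_done = _n_distinct_assignments(labels)
        p = count / n_done
    else:
        hits = 0
        for _ in range(int(n_perms)):
            pl = rng.permutation(labels)
            if stat(pl) >= phi - 1e-12:
                hits += 1
        p = (hits + 1) / (int(n_perms) + 1)
        n_done = int(n_perms)

    pct_a = 100.0 * sigma_a / total_var
    return AmovaResult(
        {"among_populations": df_a, "within_populations": df_w, "total": df_a + df_w},
        {"among_populations": ss_among, "within_populations": ss_within, "total": ss_total},
        {"among_populations": sigma_a, "within_populations": sigma_w},
        {"among_populations": pct_a, "within_populations": 100.0 - pct_a},
        phi, float(p), n_done,
    )


def _amova_two_level(d2, labels, pops, groups, n_perms, rng):
    res = _two_level_components(d2, labels, pops, groups)
    sigma_a, sigma_b, sigma_c = res["sigma"]
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        warnings.warn("zero total variance: Phi statistics undefined")
        return AmovaResult(res["df"], res["ss"], dict(zip(("a", "b", "c"), res["sigma"])),
                           {}, None, float("nan"), 0, defined=False)
    phi_st = (sigma_a + sigma_b) / total
    phi_ct = sigma_a / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else None
    n_perms = int(n_perms)

    # Phi_ST: permute individuals among populations (labels shuffled freely)
    hits_st = 0
    for _ in range(n_perms):
        pl = rng.permutation(labels)
        r = _two_level_components(d2, pl, pops, groups)
        sa, sb, sc = r["sigma"]
        tot = sa + sb + sc
        if tot != 0 and (sa + sb) / tot >= phi_st - 1e-12:
            hits_st += 1
    p_st = (hits_st + 1) / (n_perms + 1)

    # Phi_CT: permute whole populations among groups (keep pop membership)
    group_names = list(dict.fromkeys(groups[p] for p in pops))
    sizes_per_group = [sum(1 for p in pops if groups[p] == g) for g in group_names]
    hits_ct = 0
    for _ in range(n_perms):
        order = rng.permutation(pops)
        new_groups = {}
        k = 0
        for g, sz in zip(group_names, sizes_per_group):
            for p in order[k : k + sz]:
                new_groups[p] = g
            k += sz
        r = _two_level_components(d2, labels, pops, new_groups)
        sa, sb, sc = r["sigma"]
        tot = sa + sb + sc
        if tot != 0 and sa / tot >= phi_ct - 1e-12:
            hits_ct += 1
    p_ct = (hits_ct + 1) / (n_perms + 1)

    pct = {
        "among_groups": 100.0 * sigma_a / total,
        "among_populations": 100.0 * sigma_b / total,
        "within_populations": 100.0 * sigma_c / total,
    }
    return AmovaResult(
        res["df"], res["ss"],
        {"among_groups": sigma_a, "among_populations": sigma_b, "within_populations": sigma_c},
        pct, phi_st, p_st, n_perms, phi_ct=phi_ct, phi_sc=phi_sc, p_ct=p_ct, p_sc=None,
    )


def _distinct_assignments(labels: np.ndarray):
    """Yield every distinct assignment of individuals to the label multiset."""
    n = len(labels)
    pops = list(dict.fromkeys(labels.tolist()))
    sizes = {p: int((labels == p).sum()) for p in pops}

    def rec(remaining: list[int], todo: list[str], current: np.ndarray):
        if not todo:
            yield current.copy()
            return
        p = todo[0]
        for combo in combinations(remaining, sizes[p]):
            nxt = current.copy()
            nxt[list(combo)] = p
            rest = [i for i in remaining if i not in combo]
            yield from rec(rest, todo[1:], nxt)

    yield from rec(list(range(n)), pops, np.empty(n, dtype=labels.dtype))


def _n_distinct_assignments(labels: np.ndarray) -> int:
    from math import comb

    pops = list(dict.fromkeys(labels.tolist()))
    n = len(labels)
    total = 1
    left = n
    for p in pops:
        sz = int((labels == p).sum())
        total *= comb(left, sz)
        left -= sz
    return total


def pairwise_phist(
    dist_matrix_squared: np.ndarray,
    labels: list[str],
    n_perms: int = 1000,
    seed: int | None = None,
) -> PairwiseFstMatrix:
    """Pairwise population Phi_ST by two-population AMOVA for every pair.

    Values are reported as computed (negative estimates indicate more
    variation within than between populations).  p-values use the +1
    permutation correction.  Populations of size 1 are excluded.
    """
    d2 = np.asarray(dist_matrix_squared, dtype=float)
    labels = np.asarray(labels)
    _check_inputs(d2, list(labels))
    pops = list(dict.fromkeys(labels.tolist()))
    usable = []
    for p in pops:
        if (labels == p).sum() < 2:
            warnings.warn(f"population {p} has a single individual; excluded")
        else:
            usable.append(p)
    if len(usable) < 2:
        raise ValueError("need >= 2 populations of size >= 2")
    rng = np.random.default_rng(seed)
    phi = pd.DataFrame(np.nan, index=usable, columns=usable)
    pvals = pd.DataFrame(np.nan, index=usable, columns=usable)
    for a, b in combinations(usable, 2):
        idx = np.flatnonzero((labels == a) | (labels == b))
        sub = d2[np.ix_(idx, idx)]
        res = amova(sub, list(labels[idx]), n_perms=n_perms, seed=int(rng.integers(2**31)))
        phi.loc[b, a] = res.phi_st if res.phi_st is not None else 0.0
        pvals.loc[b, a] = res.p_value
    return PairwiseFstMatrix(usable, phi, pvals, n_perms)
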