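"""Reduced isolation-with-migration (IM) coalescent sampler for one locus.

Model.  An ancestral population of scaled size thetaA splits at time t into
two descendant populations of sizes theta1 and theta2 that may exchange
migrants in both directions at rates m1 and m2.  All parameters are scaled
by the per-locus mutation rate u: theta = Ne*u, t is in expected
substitutions per locus (T = t_years-in-generations * u) and m = m_rate/u.
Time runs backward from the sample; in these units each lineage accumulates
mutations at rate 1, a pair of lineages in deme i coalesces at rate
1/theta_i, and a lineage in deme i migrates (backward) at rate m_i.  Above
the split every lineage is in the single ancestral deme.

Inference.  A Metropolis-Hastings sampler explores the joint space of the
six demographic parameters (uniform priors on [0, bound]) and the structured
genealogy with its migration events.  The sequence likelihood is HKY85 with
empirical base frequencies and a fixed transition/transversion ratio
estimated from the data by a moment formula (kappa is deliberately not
sampled: the inference targets are the demographic parameters, and fixing
kappa keeps the state space small).  Move set:

* parameter scale/slide moves (the genealogy prior density changes, the
  likelihood does not);
* node-time slides within the window allowed by neighbouring events;
* lineage regrafts: detach the branch above a node and re-simulate its
  migration path and reattachment point from the exact conditional
  structured-coalescent prior given the remaining genealogy, so the
  acceptance ratio reduces to the likelihood ratio.  This move also
  regenerates the migration events of the chosen lineage, covering
  migration birth/death/move updates.

Outputs are marginal posterior histograms (fixed grids over the priors),
smoothed modes, shortest 95 % HPD intervals, autocorrelation-based effective
sample sizes, and the TMRCA (root time) trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf

from ._hky import HKYModel, estimate_kappa
from .alignio import Alignment, PopulationMap
from .diversity import empirical_base_frequencies, pairwise_differences

__all__ = [
    "IMParams",
    "IMPriors",
    "IMGenealogy",
    "IMPosterior",
    "DemographicScaling",
    "simulate_im_genealogy",
    "coalescent_log_density",
    "im_log_likelihood",
    "im_mcmc",
    "scale_to_demographic_units",
]

ANC = 2  # ancestral deme index
PARAM_NAMES = ("theta1", "theta2", "thetaA", "t", "m1", "m2")


@dataclass
class IMParams:
    theta1: float
    theta2: float
    thetaA: float
    t: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        if min(self.theta1, self.theta2, self.thetaA, self.t, self.m1, self.m2) < 0:
            raise ValueError("IM parameters must be non-negative")

    def theta_of(self, deme: int) -> float:
        return (self.theta1, self.theta2, self.thetaA)[deme]

    def m_of(self, deme: int) -> float:
        return (self.m1, self.m2)[deme]

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])


@dataclass
class IMPriors:
    """Upper bounds of independent uniform priors on [0, bound]."""

    theta1: float = 50.0
    theta2: float = 50.0
    thetaA: float = 50.0
    t: float = 10.0
    m1: float = 5.0
    m2: float = 5.0

    def bound(self, name: str) -> float:
        return float(getattr(self, name))

    def sample(self, rng: np.random.Generator) -> IMParams:
        return IMParams(*(rng.uniform(0.0, self.bound(k)) for k in PARAM_NAMES))


@dataclass
class DemographicScaling:
    """Per-locus per-generation mutation rate and mtDNA inheritance scalar."""

    u: float = 1.88e-4
    generation_years: float = 1.0
    inheritance_scalar: float = 0.25

    def __post_init__(self) -> None:
        if min(self.u, self.generation_years, self.inheritance_scalar) <= 0:
            raise ValueError("scaling fields must be positive")


class IMGenealogy:
    """Structured coalescent genealogy with migration events.

    Nodes 0..n-1 are tips (time 0); internal nodes live in slots n..2n-2.
    ``migs[v]`` lists the migration events on the edge from v to its parent
    as (time, deme-after-the-event-going-rootward) pairs in ascending time;
    all migration events are below the split time, above which every lineage
    is implicitly in the ancestral deme.
    """

    def __init__(self, n: int, parent, time, node_deme, migs, tip_labels=None):
        self.n = n
        self.parent = np.asarray(parent, dtype=int)
        self.time = np.asarray(time, dtype=float)
        self.node_deme = np.asarray(node_deme, dtype=int)
        self.migs: list[list[tuple[float, int]]] = [list(m) for m in migs]
        self.tip_labels = tip_labels or [f"t{i}" for i in range(n)]
        self.children: list[list[int]] = [[] for _ in range(2 * n - 1)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(v)
        self.root = int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def deme_at(self, v: int, s: float, t_split: float) -> int:
        """Deme of the lineage above node v at time s (time[v] <= s)."""
        if s >= t_split:
            return ANC
        d = self.node_deme[v]
        for mt, nd in self.migs[v]:
            if mt <= s:
                d = nd
            else:
                break
        return d

    def validate(self, t_split: float) -> None:
        n = self.n
        assert (self.time[:n] == 0).all(), "tips must be at time 0"
        assert set(self.node_deme[:n]) <= {0, 1}, "tips must be in demes 0/1"
        for v in range(2 * n - 1):
            p = self.parent[v]
            if p < 0:
                assert v == self.root
                assert not self.migs[v], "root carries no parent edge"
                continue
            assert self.time[p] > self.time[v], "times must increase rootward"
            prev = self.time[v]
            d = self.node_deme[v]
            assert (d == ANC) == (self.time[v] >= t_split) or v < n
            for mt, nd in self.migs[v]:
                assert self.time[v] < mt < min(self.time[p], t_split)
                assert mt > prev and nd in (0, 1) and nd != d
                prev, d = mt, nd
            assert self.deme_at(v, self.time[p], t_split) == self.node_deme[p]
        for v in range(n, 2 * n - 1):
            assert len(self.children[v]) == 2, "internal nodes must be binary"
            assert (self.node_deme[v] == ANC) == (self.time[v] >= t_split)

    def to_sim_tree(self):
        from .sim import SimTree

        demes = [int(d) for d in self.node_deme[: self.n]]
        labels = [f"d{d}_s{i}" for i, d in enumerate(demes)]
        return SimTree(
            self.n, self.parent.copy(), self.time.copy(), labels, demes, mutation_scale=1.0
        )


def simulate_im_genealogy(
    n1: int, n2: int, params: IMParams, rng: np.random.Generator
) -> IMGenealogy:
    """Draw a genealogy from the structured-coalescent prior."""
    n = n1 + n2
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    node_deme = np.concatenate([np.zeros(n1, int), np.ones(n2, int), np.full(n - 1, -9, int)])
    migs: list[list[tuple[float, int]]] = [[] for _ in range(2 * n - 1)]
    active = {0: list(range(n1)), 1: list(range(n1, n)), ANC: []}
    now, nxt = 0.0, n

    def coalesce(d: int, at: float) -> None:
        nonlocal nxt
        ix = rng.permutation(len(active[d]))[:2]
        a, b = active[d][ix[0]], active[d][ix[1]]
        parent[a] = parent[b] = nxt
        time[nxt] = at
        node_deme[nxt] = d
        active[d] = [x for x in active[d] if x not in (a, b)] + [nxt]
        nxt += 1

    def coal_rate(d: int) -> float:
        k = len(active[d])
        theta = params.theta_of(d)
        if k < 2:
            return 0.0
        if theta <= 0:
            return np.inf
        return k * (k - 1) / 2.0 / theta

    while sum(len(v) for v in active.values()) > 1:
        if now < params.t:
            rates = [
                coal_rate(0),
                coal_rate(1),
                len(active[0]) * params.m1,
                len(active[1]) * params.m2,
            ]
            if np.isinf(rates[0]) or np.isinf(rates[1]):
                coalesce(0 if np.isinf(rates[0]) else 1, now)
                continue
            total = sum(rates)
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if now + wait >= params.t:
                now = params.t
                active[ANC] = active[0] + active[1]
                active[0], active[1] = [], []
                continue
            now += wait
            pick = rng.random() * total
            if pick < rates[0]:
                coalesce(0, now)
            elif pick < rates[0] + rates[1]:
                coalesce(1, now)
            else:
                d = 0 if pick < rates[0] + rates[1] + rates[2] else 1
                v = active[d][rng.integers(len(active[d]))]
                migs[v].append((now, 1 - d))
                active[d].remove(v)
                active[1 - d].append(v)
        else:
            rate = coal_rate(ANC)
            if np.isinf(rate):
                coalesce(ANC, now)
                continue
            now += rng.exponential(1.0 / rate)
            coalesce(ANC, now)
    return IMGenealogy(n, parent, time, node_deme, migs)


def coalescent_log_density(gen: IMGenealogy, params: IMParams) -> float:
    """Log density of the genealogy (with its migration events) under the
    structured coalescent with the given parameters."""
    t_split = params.t
    events: list[tuple[float, str, int]] = []
    for v in range(gen.n, 2 * gen.n - 1):
        events.append((gen.time[v], "coal", int(gen.node_deme[v])))
    for v in range(2 * gen.n - 1):
        if gen.parent[v] < 0:
            continue
        d = int(gen.node_deme[v]) if gen.time[v] < t_split else ANC
        for mt, nd in gen.migs[v]:
            events.append((mt, "mig", d))
            d = nd
    events.sort(key=lambda e: e[0])
    k = [int((gen.node_deme[: gen.n] == 0).sum()), int((gen.node_deme[: gen.n] == 1).sum()), 0]
    now = 0.0
    crossed = False
    logp = 0.0
    thetas = (params.theta1, params.theta2, params.thetaA)
    ms = (params.m1, params.m2)

    def interval(lo: float, hi: float) -> float:
        if hi <= lo:
            return 0.0
        rate = 0.0
        if not crossed:
            for d in (0, 1):
                with np.errstate(divide="ignore"):
                    if k[d] > 1:
                        rate += k[d] * (k[d] - 1) / 2.0 / thetas[d]
                rate += k[d] * ms[d]
        else:
            rate += k[ANC] * (k[ANC] - 1) / 2.0 / thetas[ANC]
        return -(hi - lo) * rate

    for et, kind, d in events:
        if not crossed and et >= t_split:
            logp += interval(now, t_split)
            k[ANC] = k[0] + k[1]
            k[0] = k[1] = 0
            crossed = True
            now = t_split
        logp += interval(now, et)
        now = et
        if kind == "coal":
            with np.errstate(divide="ignore"):
                logp += -np.log(thetas[d]) if thetas[d] > 0 else -np.inf
            k[d] -= 1
        else:
            logp += np.log(ms[d]) if ms[d] > 0 else -np.inf
            k[d] -= 1
            k[1 - d] += 1
    return float(logp)


# ---------------------------------------------------------------------------
# likelihood


def encode_alignment(aln: Alignment) -> np.ndarray:
    """(n, L) integer codes: ACGT -> 0..3, gap/N -> 4 (missing)."""
    lut = np.full(128, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = aln.to_array()
    return lut[arr.view(np.uint32).reshape(arr.shape) & 0x7F]


def im_log_likelihood(
    gen: IMGenealogy, codes: np.ndarray, model: HKYModel
) -> float:
    """Felsenstein pruning log-likelihood of the alignment on the genealogy.

    Branch lengths are node-time differences (substitutions per locus)
    divided by the sequence length, matching the model's substitutions-per-
    site normalisation.  Site patterns are compressed once per call.
    """
    n, L = codes.shape
    if n != gen.n:
        raise ValueError("alignment size does not match genealogy tips")
    return _pruning_loglik(gen, *_compress(codes), L, model)


def _compress(codes: np.ndarray):
    patterns, weights = np.unique(codes.T, axis=0, return_counts=True)
    return patterns, weights


def _pruning_loglik(gen, patterns, weights, L, model) -> float:
    n = gen.n
    P = patterns.shape[0]
    freqs = model.stationary()
    lengths = np.zeros(2 * n - 1)
    has_parent = gen.parent >= 0
    lengths[has_parent] = (
        gen.time[gen.parent[has_parent]] - gen.time[has_parent]
    ) / L
    trans = model.transition_matrices(lengths)
    partial = np.ones((2 * n - 1, P, 4))
    eye5 = np.vstack([np.eye(4), np.ones(4)])
    for v in range(n):
        partial[v] = eye5[patterns[:, v]]
    scale = np.zeros(P)
    for v in np.argsort(gen.time[n:]) + n:
        out = np.ones((P, 4))
        for c in gen.children[v]:
            out *= partial[c] @ trans[c].T
        mx = out.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        partial[v] = out / mx[:, None]
        scale += np.log(mx)
    site_lik = partial[gen.root] @ freqs
    if (site_lik <= 0).any():
        return -np.inf
    return float((weights * (np.log(site_lik) + scale)).sum())


# ---------------------------------------------------------------------------
# MCMC moves


def _window_for_node(gen: IMGenealogy, v: int, t_split: float) -> tuple[float, float]:
    lower = 0.0
    for c in gen.children[v]:
        lower = max(lower, gen.time[c])
        if gen.migs[c]:
            lower = max(lower, gen.migs[c][-1][0])
    if gen.node_deme[v] == ANC:
        lower = max(lower, t_split)
    p = gen.parent[v]
    upper = np.inf
    if p >= 0:
        upper = gen.time[p]
    if gen.migs[v]:
        upper = min(upper, gen.migs[v][0][0])
    if gen.node_deme[v] != ANC:
        upper = min(upper, t_split)
    return lower, upper


def _move_node_time(gen, params, rng):
    """Propose a new time for one internal node; returns Hastings log-ratio
    or None if the proposal is immediately invalid."""
    v = int(rng.integers(gen.n, 2 * gen.n - 1))
    lo, hi = _window_for_node(gen, v, params.t)
    old = gen.time[v]
    if np.isfinite(hi):
        new = rng.uniform(lo, hi)
        log_hastings = 0.0
    else:
        span = old - lo
        factor = np.exp(rng.uniform(-0.7, 0.7))
        new = lo + span * factor
        log_hastings = np.log(factor)
        if span <= 0:
            return None
    if not (lo < new < (hi if np.isfinite(hi) else np.inf)):
        return None
    gen.time[v] = new
    return v, old, log_hastings


def _t_window(gen: IMGenealogy) -> tuple[float, float]:
    """Feasible range for the split time given the current genealogy."""
    lo, hi = 0.0, np.inf
    for v in range(gen.n, 2 * gen.n - 1):
        if gen.node_deme[v] == ANC:
            hi = min(hi, gen.time[v])
        else:
            lo = max(lo, gen.time[v])
    for v in range(2 * gen.n - 1):
        if gen.migs[v]:
            lo = max(lo, gen.migs[v][-1][0])
    return lo, hi


def _rescale_all(gen: IMGenealogy, params: IMParams, factor: float) -> int:
    """Scale the split time, every internal node time and every migration
    time by ``factor``; returns the number of scaled degrees of freedom
    (for the proposal Jacobian)."""
    params.t *= factor
    gen.time[gen.n :] *= factor
    n_mig = 0
    for v in range(2 * gen.n - 1):
        if gen.migs[v]:
            gen.migs[v] = [(mt * factor, nd) for mt, nd in gen.migs[v]]
            n_mig += len(gen.migs[v])
    return gen.n - 1 + n_mig + 1


class _RegraftError(Exception):
    pass


def _trunk_segments(gen: IMGenealogy, t_split: float, skip: int) -> list:
    """(start, end, deme, edge_node) segments of every edge except ``skip``'s."""
    segs = []
    for v in range(2 * gen.n - 1):
        p = gen.parent[v]
        if p < 0 or v == skip:
            continue
        lo, hi = gen.time[v], gen.time[p]
        d = int(gen.node_deme[v]) if lo < t_split else ANC
        cur = lo
        for mt, nd in gen.migs[v]:
            segs.append((cur, mt, d, v))
            cur, d = mt, nd
        if d != ANC and hi > t_split:
            segs.append((cur, t_split, d, v))
            segs.append((t_split, hi, ANC, v))
        else:
            segs.append((cur, hi, d, v))
    return segs


def _simulate_attachment(gen, c, trunk_root, params, rng, max_events=100000):
    """Simulate the detached lineage's path from the conditional prior.

    Returns (attach_edge, attach_time, deme, c_migs, ext_migs) where
    attach_edge is the trunk edge coalesced with (or trunk_root when the
    attachment happens above the old trunk root), and ext_migs are the
    migration events generated for the trunk root's extension in that case.
    """
    t_split = params.t
    s = float(gen.time[c])
    d = int(gen.node_deme[c]) if s < t_split else ANC
    segs = _trunk_segments(gen, t_split, skip=c)
    root_time = float(gen.time[trunk_root])
    c_migs: list[tuple[float, int]] = []

    # --- phase 1: against the trunk, from time[c] up to the trunk root
    if s < root_time:
        breaks = sorted(
            {t for seg in segs for t in (seg[0], seg[1])} | {t_split, root_time}
        )
        breaks = [b for b in breaks if s < b <= root_time]
        for b in breaks:
            while s < b:
                cand = [seg for seg in segs if seg[0] <= s < seg[1] and seg[2] == d]
                k = len(cand)
                theta = params.theta_of(d)
                if k and theta <= 0:
                    seg = cand[rng.integers(k)]
                    return seg[3], s, d, c_migs, None
                crate = k / theta if k else 0.0
                mrate = params.m_of(d) if (d != ANC and s < t_split) else 0.0
                total = crate + mrate
                if total <= 0:
                    s = b
                    break
                wait = rng.exponential(1.0 / total)
                if s + wait >= b:
                    s = b
                    break
                s += wait
                if rng.random() * total < crate:
                    seg = cand[rng.integers(k)]
                    return seg[3], s, d, c_migs, None
                d = 1 - d
                c_migs.append((s, d))
            if s >= t_split:
                d = ANC

    # --- phase 2: above the trunk root, paired with the root's extension
    dR = int(gen.node_deme[trunk_root]) if root_time < t_split else ANC
    ext_migs: list[tuple[float, int]] = []
    if s > root_time:
        # the detached node is older than the trunk root: the extension
        # evolves alone (migration only) over the gap
        cur = root_time
        while cur < s and dR != ANC:
            if cur >= t_split:
                dR = ANC
                break
            mrate = params.m_of(dR)
            if mrate <= 0:
                cur = min(s, t_split)
            else:
                wait = rng.exponential(1.0 / mrate)
                if cur + wait >= min(s, t_split):
                    cur = min(s, t_split)
                else:
                    cur += wait
                    dR = 1 - dR
                    ext_migs.append((cur, dR))
            if cur >= t_split:
                dR = ANC
    else:
        s = root_time
    if s >= t_split:
        d = dR = ANC
    for _ in range(max_events):
        if d == dR:
            theta = params.theta_of(d)
            if theta <= 0:
                return trunk_root, s, d, c_migs, ext_migs
            crate = 1.0 / theta
        else:
            crate = 0.0
        rates: list[float] = [crate]
        movers: list[str] = []
        if s < t_split:
            if d != ANC:
                rates.append(params.m_of(d))
                movers.append("c")
            if dR != ANC:
                rates.append(params.m_of(dR))
                movers.append("R")
        total = sum(rates)
        if total <= 0:
            # stuck in different demes with no migration: coalescence first
            # becomes possible at the split
            s = t_split
            d = dR = ANC
            continue
        wait = rng.exponential(1.0 / total)
        if s < t_split and s + wait >= t_split:
            s = t_split
            d = dR = ANC
            continue
        s += wait
        pick = rng.random() * total
        if pick < crate:
            return trunk_root, s, d, c_migs, ext_migs
        pick -= crate
        for who, r in zip(movers, rates[1:]):
            if pick < r:
                if who == "c":
                    d = 1 - d
                    c_migs.append((s, d))
                else:
                    dR = 1 - dR
                    ext_migs.append((s, dR))
                break
            pick -= r
    raise _RegraftError("attachment simulation exceeded the event budget")


def _regraft(gen: IMGenealogy, params: IMParams, rng) -> tuple | None:
    """Detach a random non-root lineage and re-attach it from the prior.

    Returns an undo closure plus bookkeeping, or None when the proposal
    failed structurally (callers treat that as a rejection).
    """
    n = gen.n
    choices = [v for v in range(2 * n - 1) if gen.parent[v] >= 0]
    c = int(choices[rng.integers(len(choices))])
    p = int(gen.parent[c])
    sib = [x for x in gen.children[p] if x != c][0]
    g = int(gen.parent[p])
    state = _snapshot(gen)
    # detach
    if g >= 0:
        gen.migs[sib] = gen.migs[sib] + gen.migs[p]
        gen.parent[sib] = g
        gen.children[g] = [sib if x == p else x for x in gen.children[g]]
    else:
        gen.parent[sib] = -1
        gen.migs[sib] = []
    gen.parent[c] = -1
    gen.parent[p] = -1  # p is a free slot until re-attachment
    gen.migs[c] = []
    gen.migs[p] = []
    gen.children[p] = []
    trunk_root = sib if gen.root == p else gen.root
    gen.root = trunk_root
    try:
        edge, att_time, d, c_migs, ext_migs = _simulate_attachment(
            gen, c, trunk_root, params, rng
        )
    except _RegraftError:
        _restore(gen, state)
        return None
    if att_time <= gen.time[c]:
        _restore(gen, state)
        return None
    # attach: reuse node id p
    gen.time[p] = att_time
    gen.node_deme[p] = d
    gen.migs[c] = c_migs
    gen.parent[c] = p
    if ext_migs is not None:
        gen.parent[trunk_root] = p
        gen.migs[trunk_root] = ext_migs
        gen.parent[p] = -1
        gen.children[p] = [c, trunk_root]
        gen.root = p
    else:
        w = int(gen.parent[edge])
        old = gen.migs[edge]
        gen.migs[edge] = [ev for ev in old if ev[0] < att_time]
        gen.migs[p] = [ev for ev in old if ev[0] > att_time]
        gen.parent[edge] = p
        gen.parent[p] = w
        gen.children[w] = [p if x == edge else x for x in gen.children[w]]
        gen.children[p] = [c, edge]
        gen.root = int(np.flatnonzero(gen.parent < 0)[0])
    return (state,)


def _snapshot(gen: IMGenealogy):
    return (
        gen.parent.copy(),
        gen.time.copy(),
        gen.node_deme.copy(),
        [list(m) for m in gen.migs],
        [list(ch) for ch in gen.children],
        gen.root,
    )


def _restore(gen: IMGenealogy, state) -> None:
    gen.parent, gen.time, gen.node_deme, migs, children, gen.root = (
        state[0].copy(),
        state[1].copy(),
        state[2].copy(),
        state[3],
        state[4],
        state[5],
    )
    gen.migs = [list(m) for m in migs]
    gen.children = [list(ch) for ch in children]


# ---------------------------------------------------------------------------
# posterior summaries


@dataclass
class IMPosterior:
    samples: pd.DataFrame
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    modes: dict[str, float]
    hpd95: dict[str, tuple[float, float]]
    ess: dict[str, float]
    n_recorded: int
    acceptance: dict[str, float] = field(default_factory=dict)
    converged: bool = True


def _histogram_summary(x: np.ndarray, upper: float, bins: int = 200):
    edges = np.linspace(0.0, upper, bins + 1)
    mass, _ = np.histogram(x, bins=edges)
    mass = mass / max(mass.sum(), 1)
    smooth = np.convolve(mass, np.ones(3) / 3.0, mode="same")
    mode = float((edges[:-1] + edges[1:])[np.argmax(smooth)] / 2.0)
    # shortest contiguous bin span holding >= 95 % of the mass
    best = (0, bins)
    i = 0
    acc = 0.0
    target = 0.95
    j = 0
    for i in range(bins):
        if i > 0:
            acc -= mass[i - 1]
        while j < bins and acc < target:
            acc += mass[j]
            j += 1
        if acc >= target and (j - i) < (best[1] - best[0]):
            best = (i, j)
    hpd = (float(edges[best[0]]), float(edges[best[1]]))
    return (edges, mass), mode, hpd


def _ess(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 10 or np.allclose(x, x[0]):
        return float(x.size)
    nlags = min(x.size // 3, 1000)
    rho = acf(x, nlags=nlags, fft=True)[1:]
    s = 0.0
    for r in rho:
        if r < 0:
            break
        s += r
    return float(x.size / (1.0 + 2.0 * s))


def im_mcmc(
    aln: Alignment,
    popmap: PopulationMap,
    priors: IMPriors | None = None,
    n_burn: int = 50_000,
    n_steps: int = 500_000,
    thin: int = 100,
    seed: int | None = None,
    params0: IMParams | None = None,
    kappa: float | None = None,
    likelihood_off: bool = False,
    ess_target: float = 500.0,
    move_weights: tuple[float, float, float, float] = (0.35, 0.25, 0.3, 0.1),
    debug: bool = False,
) -> IMPosterior:
    """Sample the IM posterior for a two-population alignment.

    ``likelihood_off`` replaces the sequence likelihood with a constant so
    the sampler targets the prior — the standard sampler-correctness check
    (each parameter's marginal must come back uniform).
    """
    priors = priors or IMPriors()
    if len(popmap.populations) != 2:
        raise ValueError("the IM model needs exactly two populations")
    rng = np.random.default_rng(seed)
    pop_of = {p: i for i, p in enumerate(popmap.populations)}
    order = sorted(range(aln.n), key=lambda i: pop_of[popmap.of(aln.ids[i])])
    aln = aln.subset([aln.ids[i] for i in order])
    demes = [pop_of[popmap.of(s)] for s in aln.ids]
    n1, n2 = demes.count(0), demes.count(1)
    codes = encode_alignment(aln)

    freqs = empirical_base_frequencies(aln)
    if kappa is None:
        kappa = _kappa_from_alignment(aln, freqs)
    model = HKYModel(freqs, kappa)

    params = params0 or priors.sample(rng)
    gen = simulate_im_genealogy(n1, n2, params, rng)

    patterns, weights = _compress(codes)

    def loglik(g):
        if likelihood_off:
            return 0.0
        return _pruning_loglik(g, patterns, weights, codes.shape[1], model)

    log_prior = coalescent_log_density(gen, params)
    log_like = loglik(gen)
    tries = 0
    while not np.isfinite(log_like + log_prior):
        params = priors.sample(rng)
        gen = simulate_im_genealogy(n1, n2, params, rng)
        log_prior = coalescent_log_density(gen, params)
        log_like = loglik(gen)
        tries += 1
        if tries > 50:
            raise RuntimeError("could not find a feasible starting state")

    records = []
    accept = {"param": 0, "time": 0, "regraft": 0, "rescale": 0}
    tried = {"param": 0, "time": 0, "regraft": 0, "rescale": 0}
    total = n_burn + n_steps
    move_p = np.asarray(move_weights, dtype=float)
    cum = np.cumsum(move_p / move_p.sum())
    for step in range(total):
        u = rng.random()
        if u < cum[0]:
            kind = "param"
            name = PARAM_NAMES[rng.integers(6)]
            old_val = getattr(params, name)
            bound = priors.bound(name)
            style = rng.random()
            if style < 1.0 / 3.0 and old_val > 0:
                factor = np.exp(rng.uniform(-0.7, 0.7))
                new_val = old_val * factor
                log_h = np.log(factor)
            elif style < 2.0 / 3.0:
                new_val = old_val + rng.uniform(-0.25, 0.25) * bound
                log_h = 0.0
            else:  # independence draw from the uniform prior
                new_val = rng.uniform(0.0, bound)
                log_h = 0.0
            tried[kind] += 1
            if not (0.0 < new_val <= bound):
                pass
            else:
                ok = True
                if name == "t":
                    lo, hi = _t_window(gen)
                    ok = lo <= new_val <= hi
                if ok:
                    setattr(params, name, new_val)
                    new_prior = coalescent_log_density(gen, params)
                    if np.log(rng.random()) < new_prior - log_prior + log_h:
                        log_prior = new_prior
                        accept[kind] += 1
                    else:
                        setattr(params, name, old_val)
        elif u < cum[1]:
            kind = "time"
            tried[kind] += 1
            out = _move_node_time(gen, params, rng)
            if out is not None:
                v, old_t, log_h = out
                new_prior = coalescent_log_density(gen, params)
                new_like = loglik(gen)
                if np.log(rng.random()) < (
                    new_prior - log_prior + new_like - log_like + log_h
                ):
                    log_prior, log_like = new_prior, new_like
                    accept[kind] += 1
                else:
                    gen.time[v] = old_t
        elif u < cum[2]:
            kind = "regraft"
            tried[kind] += 1
            out = _regraft(gen, params, rng)
            if out is not None:
                (state,) = out
                new_like = loglik(gen)
                if np.log(rng.random()) < new_like - log_like:
                    log_like = new_like
                    log_prior = coalescent_log_density(gen, params)
                    accept[kind] += 1
                else:
                    _restore(gen, state)
        else:
            kind = "rescale"
            tried[kind] += 1
            factor = np.exp(rng.uniform(-0.5, 0.5))
            if params.t * factor <= priors.bound("t"):
                state = _snapshot(gen)
                old_t = params.t
                dof = _rescale_all(gen, params, factor)
                new_prior = coalescent_log_density(gen, params)
                new_like = loglik(gen)
                if np.log(rng.random()) < (
                    new_prior - log_prior + new_like - log_like + dof * np.log(factor)
                ):
                    log_prior, log_like = new_prior, new_like
                    accept[kind] += 1
                else:
                    _restore(gen, state)
                    params.t = old_t
        if debug:
            gen.validate(params.t)
            assert np.isclose(
                coalescent_log_density(gen, params), log_prior, atol=1e-6
            )
        if step >= n_burn and (step - n_burn) % thin == 0:
            records.append(params.as_array().tolist() + [gen.tmrca])

    cols = list(PARAM_NAMES) + ["tmrca"]
    samples = pd.DataFrame(records, columns=cols)
    histograms, modes, hpd95, ess = {}, {}, {}, {}
    for name in PARAM_NAMES:
        upper = priors.bound(name)
        histograms[name], modes[name], hpd95[name] = _histogram_summary(
            samples[name].to_numpy(), upper
        )
        ess[name] = _ess(samples[name].to_numpy())
    tm = samples["tmrca"].to_numpy()
    histograms["tmrca"], modes["tmrca"], hpd95["tmrca"] = _histogram_summary(
        tm, float(tm.max()) * 1.02 + 1e-9
    )
    ess["tmrca"] = _ess(tm)
    converged = all(e >= ess_target for e in ess.values())
    if not converged:
        warnings.warn(
            f"effective sample sizes below target {ess_target}: "
            + ", ".join(f"{k}={v:.0f}" for k, v in ess.items() if v < ess_target)
        )
    rates = {k: accept[k] / max(tried[k], 1) for k in accept}
    return IMPosterior(samples, histograms, modes, hpd95, ess, len(samples), rates, converged)


def _kappa_from_alignment(aln: Alignment, freqs) -> float:
    arr = aln.to_array()
    valid = (arr != "-") & (arr != "N")
    n = aln.n
    ts_tot = tv_tot = comp_tot = 0
    purine = np.isin(arr, list("AG"))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            diff = both & (arr[i] != arr[j])
            same_class = purine[i] == purine[j]
            ts_tot += int((diff & same_class).sum())
            tv_tot += int((diff & ~same_class).sum())
            comp_tot += int(both.sum())
    if comp_tot == 0:
        return 2.0
    return estimate_kappa(ts_tot / comp_tot, tv_tot / comp_tot, freqs)


def scale_to_demographic_units(
    posterior: IMPosterior, scaling: DemographicScaling
) -> dict[str, float]:
    """Convert posterior modes to calendar years and effective sizes.

    Divergence and TMRCA: years = mode / u * generation_years.  Effective
    (female) population sizes: Ne = theta / u under the theta = Ne*u scaling;
    a species-level effective size is Ne divided by the mtDNA inheritance
    scalar.  Year figures are also reported rounded to the nearest 100.
    """
    u = scaling.u
    out = {
        "divergence_years": posterior.modes["t"] / u * scaling.generation_years,
        "tmrca_years": posterior.modes["tmrca"] / u * scaling.generation_years,
    }
    for name in ("theta1", "theta2", "thetaA"):
        out[f"Ne_{name}"] = posterior.modes[name] / u
        out[f"Ne_species_{name}"] = posterior.modes[name] / u / scaling.inheritance_scalar
    out["divergence_years_rounded"] = round(out["divergence_years"] / 100.0) * 100.0
    out["tmrca_years_rounded"] = round(out["tmrca_years"] / 100.0) * 100.0
    return out
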