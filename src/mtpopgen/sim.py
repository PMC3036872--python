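"""Coalescent simulation of control-region-like datasets.

Three demographic scenarios are supported:

``constant``
    Neutral, constant-size: each pair of lineages coalesces at rate 1/theta
    in mutational time, so the expected coalescence time of a sample of two is
    theta and the equilibrium mean number of pairwise differences is theta.
``sudden_expansion``
    The sudden-expansion model behind the mismatch distribution: pairwise
    coalescence rate 1/theta1 more recently than tau, 1/theta0 earlier.
``im_split``
    Two descendant demes exchanging migrants that merge into an ancestral
    deme at a divergence time t (isolation-with-migration); delegated to
    :mod:`mtpopgen.im`, which owns the structured genealogy type.

Time units.  For ``constant`` and ``sudden_expansion`` node times are in
mutational time (the unit in which the expansion age tau is expressed), where
a branch of duration dt carries Poisson(dt/2) mutations, so a pair separated
at depth T differs at Poisson(T) sites.  For ``im_split`` node times are in
expected substitutions per locus (the unit of the scaled divergence time
T = t*mu), where each lineage mutates at rate 1.  The ``mutation_scale``
attribute of a genealogy records the factor converting a time interval into
expected substitutions per sequence, so exported branch lengths are always in
substitutions-per-sequence units regardless of scenario.

Sequence evolution is HKY85 (AT-rich control-region base composition by
default) with optional gamma and invariant-sites rate multipliers.  Indels
are not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._hky import HKYModel
from .alignio import Alignment, PopulationMap

__all__ = [
    "SimConfig",
    "SimTree",
    "SimOutput",
    "simulate_genealogy",
    "evolve_sequences",
    "simulate_dataset",
    "branch_mutation_counts",
    "pairwise_diffs_from_mutations",
    "count_haplotypes_from_mutations",
    "simulate_pairwise_diffs",
]

#: average control-region base composition (A, C, G, T) of the study system,
#: renormalised to sum exactly to 1
_RAW = (0.3725, 0.0957, 0.0793, 0.4524)
AT_RICH_FREQS = tuple(x / sum(_RAW) for x in _RAW)


@dataclass
class SimConfig:
    """Scenario and parameters for one synthetic dataset.

    ``n`` may be a single sample size or one size per deme; for the panmictic
    scenarios multiple demes are labels painted on one genealogy (the
    situation the study's AMOVA found), for ``im_split`` exactly two demes are
    sampled from the structured genealogy.
    """

    scenario: str = "constant"
    n: int | Sequence[int] = 20
    L: int = 993
    theta: float = 7.5
    theta0: float = 0.03
    theta1: float = 62.6
    tau: float = 9.17
    theta2: float = 10.0
    thetaA: float = 5.0
    t_split: float = 1.0
    m1: float = 0.0
    m2: float = 0.0
    freqs: tuple[float, float, float, float] = AT_RICH_FREQS
    kappa: float = 20.0
    gamma_alpha: float | None = None
    invariant_fraction: float = 0.0
    seed: int | None = None

    def sizes(self) -> list[int]:
        return [int(self.n)] if np.isscalar(self.n) else [int(x) for x in self.n]

    def __post_init__(self) -> None:
        if self.scenario not in ("constant", "sudden_expansion", "im_split"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(s < 1 for s in self.sizes()) or sum(self.sizes()) < 2:
            raise ValueError("need at least two samples")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.scenario == "im_split" and len(self.sizes()) != 2:
            raise ValueError("im_split needs exactly two demes")


@dataclass
class SimTree:
    """A binary coalescent genealogy over ``n_tips`` samples.

    Nodes 0..n-1 are tips at time 0; internal nodes are numbered onward in
    coalescence order with the root last.  ``mutation_scale`` converts a time
    interval to expected substitutions per sequence.
    """

    n_tips: int
    parent: np.ndarray
    time: np.ndarray
    tip_labels: list[str]
    tip_demes: list[int]
    mutation_scale: float = 0.5

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def branch_subs(self) -> np.ndarray:
        """Expected substitutions per sequence on each node's parent edge."""
        b = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        b[has_parent] = (self.time[self.parent[has_parent]] - self.time[has_parent])
        return b * self.mutation_scale

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def newick(self) -> str:
        ch = self.children()
        subs = self.branch_subs()

        def fmt(v: int) -> str:
            if v < self.n_tips:
                name = self.tip_labels[v]
            else:
                name = ""
            if ch[v]:
                inner = ",".join(fmt(c) for c in ch[v])
                body = f"({inner}){name}"
            else:
                body = name
            if self.parent[v] >= 0:
                return f"{body}:{subs[v]:.8g}"
            return body

        return fmt(self.root) + ";"


@dataclass
class SimOutput:
    alignment: Alignment
    popmap: PopulationMap
    tree: SimTree
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alignment.fasta",
            "popmap": outdir / "popmap.tsv",
            "newick": outdir / "genealogy.nwk",
            "truth": outdir / "truth.json",
        }
        with open(paths["fasta"], "w") as fh:
            for sid, seq in zip(self.alignment.ids, self.alignment.seqs):
                fh.write(f">{sid}\n{seq}\n")
        with open(paths["popmap"], "w") as fh:
            for sid in self.alignment.ids:
                fh.write(f"{sid}\t{self.popmap.of(sid)}\n")
        paths["newick"].write_text(self.tree.newick() + "\n")
        paths["truth"].write_text(json.dumps(asdict(self.config), default=list, indent=1))
        return paths


def _rng(config: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def _pair_rate(t: float, config: SimConfig) -> float:
    """Coalescence rate per lineage pair at time t (panmictic scenarios)."""
    if config.scenario == "constant":
        return 1.0 / config.theta
    if t < config.tau:
        return 1.0 / max(config.theta1, 1e-300)
    return 1.0 / max(config.theta0, 1e-300)


def simulate_genealogy(config: SimConfig, rng: np.random.Generator | None = None) -> SimTree:
    """Draw one genealogy under the configured scenario."""
    rng = _rng(config, rng)
    if config.scenario == "im_split":
        from .im import IMParams, simulate_im_genealogy

        n1, n2 = config.sizes()
        params = IMParams(
            config.theta1, config.theta2, config.thetaA, config.t_split, config.m1, config.m2
        )
        gen = simulate_im_genealogy(n1, n2, params, rng)
        return gen.to_sim_tree()

    sizes = config.sizes()
    n = sum(sizes)
    demes = [d for d, s in enumerate(sizes) for _ in range(s)]
    labels = [f"d{demes[i]}_s{i}" for i in range(n)]
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    now = 0.0
    nxt = n
    # epoch boundary only matters for sudden_expansion
    boundary = config.tau if config.scenario == "sudden_expansion" else np.inf
    while len(active) > 1:
        k = len(active)
        total = k * (k - 1) / 2.0 * _pair_rate(now, config)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if now < boundary <= now + wait:
            # re-draw the waiting time under the pre-expansion rate
            now = boundary
            boundary = np.inf
            continue
        now += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = now
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return SimTree(n, parent, time, labels, demes, mutation_scale=0.5)


def evolve_sequences(
    tree: SimTree,
    model: HKYModel,
    L: int,
    rng: np.random.Generator,
    gamma_alpha: float | None = None,
    invariant_fraction: float = 0.0,
) -> Alignment:
    """Evolve sequences down ``tree`` under ``model``.

    Branch lengths are the tree's expected substitutions per sequence; the
    per-site length is that divided by ``L``.  Gamma and invariant-sites rate
    variation enter as per-site multipliers normalised to mean 1.
    """
    rates = np.ones(L)
    if gamma_alpha is not None:
        rates = rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=L)
    if invariant_fraction > 0:
        inv = rng.random(L) < invariant_fraction
        rates = np.where(inv, 0.0, rates) / (1.0 - invariant_fraction)
    freqs = model.stationary()
    subs = tree.branch_subs()
    ch = tree.children()
    states = np.empty((tree.n_nodes, L), dtype=np.int8)
    root = tree.root
    states[root] = rng.choice(4, size=L, p=freqs)
    # pre-order traversal
    stack = [root]
    while stack:
        v = stack.pop()
        for c in ch[v]:
            t_sites = subs[c] / L * rates
            E = np.exp(t_sites[:, None] * model._lam[None, :])
            # per-site transition rows for the parent state only
            U_rows = model._U[states[v]]  # (L, 4)
            probs = np.einsum("sk,sk,kj->sj", U_rows, E, model._Vinv)
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(L)
            states[c] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            stack.append(c)
    seqs = tuple("".join("ACGT"[b] for b in states[i]) for i in range(tree.n_tips))
    return Alignment(tuple(tree.tip_labels), seqs)


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimOutput:
    """Genealogy + sequences + population map for one synthetic dataset."""
    rng = _rng(config, rng)
    tree = simulate_genealogy(config, rng)
    model = HKYModel(config.freqs, config.kappa)
    aln = evolve_sequences(
        tree, model, config.L, rng, config.gamma_alpha, config.invariant_fraction
    )
    assignments = {
        lbl: f"pop{d}" for lbl, d in zip(tree.tip_labels, tree.tip_demes)
    }
    npop = len(set(tree.tip_demes))
    popmap = PopulationMap(assignments, tuple(f"pop{d}" for d in range(npop)))
    return SimOutput(aln, popmap, tree, config)


# ---------------------------------------------------------------------------
# infinite-sites helpers (mutation counts on branches, no sequences)


def branch_mutation_counts(
    tree: SimTree, rng: np.random.Generator, total: int | None = None
) -> np.ndarray:
    """Mutation counts per branch: Poisson with the branch's expected
    substitutions, or exactly ``total`` placed multinomially by length."""
    subs = tree.branch_subs()
    if total is None:
        return rng.poisson(subs)
    tot = subs.sum()
    if tot <= 0:
        return np.zeros_like(subs, dtype=int)
    return rng.multinomial(total, subs / tot)


def _tip_indicator(tree: SimTree) -> np.ndarray:
    """(n_nodes, n_tips) boolean: tip j descends from (or is) node i."""
    ind = np.zeros((tree.n_nodes, tree.n_tips), dtype=bool)
    ind[np.arange(tree.n_tips), np.arange(tree.n_tips)] = True
    for v in np.argsort(tree.time):
        p = tree.parent[v]
        if p >= 0:
            ind[p] |= ind[v]
    return ind


def pairwise_diffs_from_mutations(tree: SimTree, muts: np.ndarray) -> np.ndarray:
    """Pairwise difference matrix implied by per-branch mutation counts
    (infinite sites: every mutation is visible in all descendant tips)."""
    ind = _tip_indicator(tree)
    n = tree.n_tips
    d = np.zeros((n, n))
    for v in np.flatnonzero(muts):
        if tree.parent[v] < 0:
            continue
        a = ind[v]
        d += muts[v] * (a[:, None] ^ a[None, :])
    return d


def count_haplotypes_from_mutations(tree: SimTree, muts: np.ndarray) -> int:
    """Number of distinct tip haplotypes implied by per-branch mutations."""
    label = np.zeros(tree.n_nodes, dtype=int)
    fresh = 0
    for v in np.argsort(-tree.time):  # root first
        p = tree.parent[v]
        if p < 0:
            continue
        if muts[v] > 0:
            fresh += 1
            label[v] = fresh
        else:
            label[v] = label[p]
    return len(set(label[: tree.n_tips].tolist()))


def simulate_pairwise_diffs(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """One dataset's pairwise-difference matrix under the infinite-sites
    approximation (used by the mismatch parametric bootstrap)."""
    tree = simulate_genealogy(config, rng)
    muts = branch_mutation_counts(tree, rng)
    return pairwise_diffs_from_mutations(tree, muts)
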