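"""Minimum spanning tree / network of haplotypes.

Haplotypes are connected by edges weighted with their raw substitution-count
differences, mirroring genealogical tick-mark plots.  Kruskal's algorithm
with deterministic tie-breaking (weight, then lexicographic haplotype-id
pair) yields the minimum spanning tree; every non-tree edge whose weight
equals the maximum edge weight on the tree path between its endpoints is an
equally-minimal alternative connection, and flagging those turns the tree
into a minimum spanning network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .alignio import HaplotypeTable

__all__ = ["NetworkEdge", "minimum_spanning_network", "network_to_dataframe", "write_graphml"]


@dataclass(frozen=True)
class NetworkEdge:
    haplotype_a: int
    haplotype_b: int
    n_substitutions: int
    in_mst: bool
    alternative: bool


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_network(
    hap_table: HaplotypeTable, diff_matrix: np.ndarray
) -> list[NetworkEdge]:
    """MST edges plus equally-minimal alternative edges between haplotypes.

    ``diff_matrix`` is the integer substitution-count matrix between the
    table's K haplotypes (row/column order = haplotype id order).
    """
    d = np.asarray(diff_matrix)
    K = hap_table.k
    if d.shape != (K, K):
        raise ValueError("difference matrix must be K x K over the haplotypes")
    if K == 1:
        warnings.warn("single haplotype: empty network")
        return []
    ids = list(hap_table.counts.index)
    candidates = sorted(
        ((int(round(d[i, j])), i, j) for i in range(K) for j in range(i + 1, K)),
        key=lambda e: (e[0], ids[e[1]], ids[e[2]]),
    )
    uf = _UnionFind(K)
    tree = nx.Graph()
    mst_pairs = set()
    for w, i, j in candidates:
        if uf.union(i, j):
            tree.add_edge(i, j, weight=w)
            mst_pairs.add((i, j))
    edges: list[NetworkEdge] = []
    for w, i, j in candidates:
        if (i, j) in mst_pairs:
            edges.append(NetworkEdge(ids[i], ids[j], w, True, False))
        else:
            path = nx.shortest_path(tree, i, j)
            path_max = max(
                tree.edges[a, b]["weight"] for a, b in zip(path, path[1:])
            )
            if w == path_max:
                edges.append(NetworkEdge(ids[i], ids[j], w, False, True))
    return edges


def network_to_dataframe(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "haplotype_a": e.haplotype_a,
                "haplotype_b": e.haplotype_b,
                "n_substitutions": e.n_substitutions,
                "in_mst": e.in_mst,
                "alternative": e.alternative,
            }
            for e in edges
        ]
    )


def write_graphml(
    edges: list[NetworkEdge], hap_table: HaplotypeTable, path: str
) -> None:
    """GraphML export with per-population counts and total frequency (node
    size metadata for plotting) attached to every haplotype node."""
    g = nx.Graph()
    for hap_id in hap_table.counts.index:
        row = hap_table.counts.loc[hap_id]
        g.add_node(
            int(hap_id),
            frequency=int(row.sum()),
            **{f"count_{p}": int(row[p]) for p in hap_table.counts.columns},
        )
    for e in edges:
        g.add_edge(
            e.haplotype_a,
            e.haplotype_b,
            weight=e.n_substitutions,
            in_mst=e.in_mst,
            alternative=e.alternative,
        )
    nx.write_graphml(g, path)
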