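"""Functional-module detection by k-clique percolation (CPM).

A module is the union of all k-cliques reachable from one another through
adjacency, where two k-cliques are adjacent iff they share exactly k-1
nodes.  Modules therefore contain at least k genes and may overlap in
genes — the property that distinguishes CPM from partitioning methods.
Edge sign is ignored by default (the graph is treated as unsigned simple);
a positive-only mode restricts to positively coexpressed edges.

k-cliques are derived from maximal cliques for speed, but the output
contract is the brute-force definition: every fully connected k-node set,
exactly once, in canonical (sorted-tuple) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class Module:
    """A CPM community: the union of one connected set of k-cliques."""

    module_id: str
    k: int
    genes: frozenset[str]
    clique_count: int

    @property
    def size(self) -> int:
        return len(self.genes)


def _as_graph(network, positive_only: bool = False) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    edges = network.edges
    if positive_only and "sign" in edges.columns:
        edges = edges[edges["sign"] == "positive"]
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    return g


def enumerate_k_cliques(network, k: int, positive_only: bool = False) -> list[tuple]:
    """All k-node cliques of the (unsigned, simple) graph, canonically ordered."""
    if k < 3:
        raise ValueError("k must be >= 3")
    g = _as_graph(network, positive_only)
    cliques: set[tuple] = set()
    for maximal in nx.find_cliques(g):
        if len(maximal) < k:
            continue
        for sub in combinations(sorted(maximal), k):
            cliques.add(sub)
    return sorted(cliques)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def clique_percolation(network, k: int, positive_only: bool = False) -> list[Module]:
    """CPM communities: components of the k-clique adjacency graph.

    Two distinct k-cliques can share at most k-1 nodes, so indexing cliques
    by their (k-1)-subsets finds exactly the pairs sharing k-1 nodes.
    """
    cliques = enumerate_k_cliques(network, k, positive_only)
    uf = _UnionFind(len(cliques))
    by_subset: dict[tuple, int] = {}
    for idx, clique in enumerate(cliques):
        for sub in combinations(clique, k - 1):
            first = by_subset.setdefault(sub, idx)
            if first != idx:
                uf.union(first, idx)
    groups: dict[int, list[int]] = {}
    for idx in range(len(cliques)):
        groups.setdefault(uf.find(idx), []).append(idx)
    raw = []
    for members in groups.values():
        genes: set[str] = set()
        for idx in members:
            genes.update(cliques[idx])
        raw.append((tuple(sorted(genes)), len(members)))
    raw.sort()
    return [
        Module(module_id=f"M{i + 1:04d}", k=k, genes=frozenset(genes), clique_count=count)
        for i, (genes, count) in enumerate(raw)
    ]


@dataclass
class KScanRow:
    k: int
    module_count: int
    covered_genes: int
    coverage_fraction: float


def scan_k(network, k_min: int = 3, k_max: int = 8, positive_only: bool = False) -> tuple[list[KScanRow], int]:
    """Module count and gene coverage per k, plus a recommended k.

    The recommendation maximizes (coverage, module count) lexicographically
    and is advisory only; coverage is monotone non-increasing in k, so the
    composite mostly rewards the smallest k that still yields many modules.
    """
    if not 3 <= k_min <= k_max:
        raise ValueError("need 3 <= k_min <= k_max")
    g = _as_graph(network, positive_only)
    n_nodes = g.number_of_nodes()
    if n_nodes == 0:
        raise ValueError("empty network")
    rows = []
    for k in range(k_min, k_max + 1):
        modules = clique_percolation(g, k)
        covered = set().union(*(m.genes for m in modules)) if modules else set()
        rows.append(
            KScanRow(
                k=k,
                module_count=len(modules),
                covered_genes=len(covered),
                coverage_fraction=len(covered) / n_nodes,
            )
        )
    best = max(rows, key=lambda r: (r.coverage_fraction, r.module_count))
    return rows, best.k


def modules_to_frame(modules: list[Module]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [m.module_id for m in modules],
            "k": [m.k for m in modules],
            "size": [m.size for m in modules],
            "genes": [",".join(sorted(m.genes)) for m in modules],
        }
    )


def read_modules_tsv(path) -> list[Module]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Module(
            module_id=row.module_id,
            k=int(row.k),
            genes=frozenset(row.genes.split(",")),
            clique_count=0,
        )
        for row in df.itertuples()
    ]
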