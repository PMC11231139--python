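"""Minimum-spanning haplotype networks and their summaries.

Haplotypes are joined by a minimum-spanning tree over their Hamming
distances (mutational steps). Ties are broken deterministically and
equal-weight alternative connections are recorded rather than silently
dropped, since ambiguous minimum-spanning connections are part of the
result for shallow mtDNA data.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeTable

__all__ = ["HaplotypeNetwork", "build_network", "network_summary", "hamming_matrix"]


def hamming_matrix(patterns: tuple[str, ...]) -> np.ndarray:
    """Pairwise Hamming distances between haplotype site patterns."""
    arrs = np.array([list(p) for p in patterns], dtype="U1")
    n = len(patterns)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i + 1:] = (arrs[i] != arrs[i + 1:]).sum(axis=1)
        d[i + 1:, i] = d[i, i + 1:]
    return d


@dataclass(frozen=True)
class HaplotypeNetwork:
    graph: nx.Graph  # the chosen spanning tree; nodes carry counts
    alternative_edges: tuple[tuple[str, str, int], ...]
    table: HaplotypeTable

    @property
    def total_weight(self) -> int:
        return sum(d["steps"] for _, _, d in self.graph.edges(data=True))

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"hap_a": a, "hap_b": b, "steps": d["steps"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["hap_a", "hap_b", "steps"])

    def node_table(self) -> pd.DataFrame:
        df = self.table.to_frame()
        df.insert(0, "degree", [self.graph.degree(h) for h in df.index])
        return df

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for a, b, steps in self.alternative_edges:
            g.add_edge(a, b, steps=int(steps), alternative=True)
        nx.write_graphml(g, path)


def build_network(table: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum-spanning tree over the haplotype Hamming-distance matrix.

    Kruskal with lexicographic tie-breaking on (steps, hap_a, hap_b) so the
    chosen tree is reproducible; non-tree edges whose weight equals the
    maximum tree-edge weight on the path between their endpoints are
    recorded as equally minimal alternatives.
    """
    ids = table.haplotype_ids
    n = len(ids)
    g = nx.Graph()
    counts = table.global_counts()
    for i, h in enumerate(ids):
        g.add_node(
            h,
            count=int(counts[i]),
            frequency=float(counts[i] / table.total_n),
        )
    if n == 1:
        return HaplotypeNetwork(g, (), table)
    d = hamming_matrix(table.site_patterns)

    def sort_key(i: int, j: int):
        a, b = sorted((ids[i], ids[j]))
        return (d[i, j], a, b)

    edges = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: sort_key(*e),
    )
    # Kruskal with union-find
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            g.add_edge(ids[i], ids[j], steps=int(d[i, j]))
    # alternative minimum edges: same weight as the path-max in the tree
    alternatives = []
    for i, j in edges:
        a, b = ids[i], ids[j]
        if g.has_edge(a, b):
            continue
        path = nx.shortest_path(g, a, b)
        path_max = max(g.edges[u, v]["steps"] for u, v in zip(path, path[1:]))
        if d[i, j] == path_max:
            alternatives.append((*sorted((a, b)), int(d[i, j])))
    return HaplotypeNetwork(g, tuple(alternatives), table)


def network_summary(net: HaplotypeNetwork) -> dict:
    """Dominant-haplotype shares, maximum step count and node classification.

    Shares are percentages of all sampled individuals; a node is classified
    internal when its tree degree is >= 2, otherwise a tip.
    """
    counts = net.table.global_counts()
    total = net.table.total_n
    order = np.argsort(-counts, kind="stable")
    shares = {
        net.table.haplotype_ids[i]: 100.0 * counts[i] / total for i in order
    }
    steps = [d["steps"] for _, _, d in net.graph.edges(data=True)]
    classification = {
        h: ("internal" if net.graph.degree(h) >= 2 else "tip")
        for h in net.table.haplotype_ids
    }
    dominant = net.table.haplotype_ids[order[0]]
    return {
        "shares_pct": shares,
        "dominant": dominant,
        "dominant_share_pct": shares[dominant],
        "max_steps": max(steps) if steps else 0,
        "classification": classification,
    }
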