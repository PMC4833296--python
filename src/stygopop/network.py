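"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are connected agglomeratively in increasing mutational-step
order up to a connection limit chosen so that, with probability >= alpha
(0.95 by default), the implied multi-step path is free of homoplasy.
Connections longer than one step are realized through inferred
(unsampled) intermediate nodes; equal-length alternative connections
are retained as loops and flagged rather than resolved, since any
resolution rule is arbitrary without outgroup information.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j observed differences over L sites are homoplasy-free.

    Under uniform placement of mutations across sites, a j-step
    difference is parsimonious when all j underlying mutations struck
    distinct sites (no superimposed or parallel change), which has
    probability prod_{i=1}^{j-1} (1 - i/L).
    """
    if j < 1:
        return 1.0
    i = np.arange(1, min(j, L))
    return float(np.prod(1.0 - i / L))


def parsimony_limit(L: int, alpha: float = 0.95) -> int:
    """Largest step count whose parsimonious-connection probability >= alpha."""
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    j = 1
    while j < L and parsimony_probability(j + 1, L) >= alpha:
        j += 1
    return j


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph          # nodes: haplotype ids; attr inferred=True for medians
    limit: int

    @property
    def components(self) -> list:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def observed_nodes(self) -> list:
        return [v for v, d in self.graph.nodes(data=True) if not d.get("inferred")]

    @property
    def loops(self) -> list:
        """Edges whose removal leaves endpoints connected (ambiguity loops)."""
        return _loop_edges(self.graph)

    def path_steps(self, a, b) -> int:
        return nx.shortest_path_length(self.graph, a, b)

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tinferred_a\tinferred_b\n")
            for u, v in self.graph.edges:
                ia = int(bool(self.graph.nodes[u].get("inferred")))
                ib = int(bool(self.graph.nodes[v].get("inferred")))
                fh.write(f"{u}\t{v}\t{ia}\t{ib}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph haplotypes {\n")
            for v, d in self.graph.nodes(data=True):
                shape = "point" if d.get("inferred") else "circle"
                fh.write(f'  "{v}" [shape={shape}];\n')
            for u, v in self.graph.edges:
                fh.write(f'  "{u}" -- "{v}";\n')
            fh.write("}\n")


def _loop_edges(g: nx.Graph) -> list:
    out = []
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        if nx.has_path(g, u, v):
            out.append((u, v))
        g.add_edge(u, v)
    return out


def build_network(
    t: HaplotypeTable, limit: int | None = None, alpha: float = 0.95
) -> HaplotypeNetwork:
    """Agglomerative statistical-parsimony network of a haplotype table.

    Pairs of haplotypes are considered in increasing Hamming-distance
    order up to ``limit`` (computed from the alignment length when not
    given).  A pair joins the network when its two haplotypes are in
    different components at the start of its distance level; all joining
    pairs of one level are added, so equal-length alternatives survive
    as loops.  Ties within a level are ordered by descending total
    haplotype frequency, then lexicographic id, for determinism.
    """
    if t.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if limit is None:
        limit = parsimony_limit(t.total_length, alpha)
    d = t.diff_matrix()
    freq = t.counts.sum(axis=1)
    ids = [f"H{i + 1}" for i in range(t.n_haplotypes)]
    g = nx.Graph()
    for i, hid in enumerate(ids):
        g.add_node(hid, inferred=False, haplotype=t.haplotypes[i], count=int(freq[i]))

    comp = {hid: k for k, hid in enumerate(ids)}  # component labels, relabel on union
    n_median = 0
    for level in sorted(set(d[np.triu_indices_from(d, 1)].tolist())):
        if level == 0 or level > limit:
            continue
        comp_start = dict(comp)
        pairs = [
            (i, j)
            for i in range(t.n_haplotypes)
            for j in range(i + 1, t.n_haplotypes)
            if d[i, j] == level and comp_start[ids[i]] != comp_start[ids[j]]
        ]
        pairs.sort(key=lambda p: (-(freq[p[0]] + freq[p[1]]), ids[p[0]], ids[p[1]]))
        for i, j in pairs:
            # components distinct at level start: connect; equal-length
            # alternatives that re-bridge an already-merged pair form loops
            prev = ids[i]
            for _ in range(1, int(level)):
                n_median += 1
                mid = f"m{n_median}"
                g.add_node(mid, inferred=True)
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, ids[j], steps=1)
            ci, cj = comp[ids[i]], comp[ids[j]]
            if ci != cj:
                lo, hi = min(ci, cj), max(ci, cj)
                for v in comp:
                    if comp[v] == hi:
                        comp[v] = lo
    return HaplotypeNetwork(graph=g, limit=int(limit))


@dataclass
class GroupSeparation:
    hamming_min: int
    path_min: float  # inf when the groups sit in different components


def min_steps_between_groups(
    net: HaplotypeNetwork,
    t: HaplotypeTable,
    grouping: dict,
    group_a: str,
    group_b: str,
) -> GroupSeparation:
    """Minimum mutational separation between two groups' haplotypes.

    Reports both the raw minimum pairwise Hamming distance over variable
    sites and the minimum network path length (in single-step edges,
    counting inferred intermediates).
    """
    for g in (group_a, group_b):
        if g not in grouping:
            raise KeyError(f"unknown group {g!r}")
    deme_idx = {d: j for j, d in enumerate(t.deme_ids)}
    d = t.diff_matrix()
    ids = [f"H{i + 1}" for i in range(t.n_haplotypes)]

    def haps_of(g):
        idx = [deme_idx[dm] for dm in grouping[g]]
        return np.nonzero(t.counts[:, idx].sum(axis=1) > 0)[0]

    ha, hb = haps_of(group_a), haps_of(group_b)
    if len(ha) == 0 or len(hb) == 0:
        raise ValueError("group without haplotypes")
    hamming = int(d[np.ix_(ha, hb)].min())
    path = np.inf
    for i in ha:
        lengths = nx.single_source_shortest_path_length(net.graph, ids[i])
        for j in hb:
            if ids[j] in lengths:
                path = min(path, lengths[ids[j]])
    return GroupSeparation(hamming_min=hamming, path_min=path)
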