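"""Hierarchical AMOVA and SAMOVA spatial clustering.

AMOVA follows the Excoffier, Smouse & Quattro (1992) three-level
variance decomposition on squared intersequence distances (here the
number of pairwise nucleotide differences, the standard choice for
sequence data).  SAMOVA searches, by simulated annealing, for the
partition of demes into K geographically contiguous groups that
maximizes the among-group fixation index F_CT, with contiguity defined
by a Delaunay neighbourhood graph of deme coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .haplotypes import HaplotypeTable, SampleMetadata


@dataclass
class GroupingPartition:
    deme_ids: list
    group_of: dict  # deme -> group index (0..K-1)

    def __post_init__(self):
        missing = [d for d in self.deme_ids if d not in self.group_of]
        if missing:
            raise ValueError(f"unassigned demes: {missing}")
        ks = sorted(set(self.group_of[d] for d in self.deme_ids))
        if ks != list(range(len(ks))):
            raise ValueError("group indices must be 0..K-1 with no empty group")

    @property
    def K(self) -> int:
        return len(set(self.group_of[d] for d in self.deme_ids))

    def groups(self) -> list:
        out = [[] for _ in range(self.K)]
        for d in self.deme_ids:
            out[self.group_of[d]].append(d)
        return out

    def canonical(self) -> tuple:
        """Relabel groups by first occurrence; used for deterministic ties."""
        seen: dict = {}
        lab = []
        for d in self.deme_ids:
            g = self.group_of[d]
            if g not in seen:
                seen[g] = len(seen)
            lab.append(seen[g])
        return tuple(lab)

    @classmethod
    def from_groups(cls, grouping: dict, deme_ids=None) -> "GroupingPartition":
        """Build from ``{group_id: [deme, ...]}`` (group order = dict order)."""
        g_of = {}
        for k, (g, demes) in enumerate(grouping.items()):
            for d in demes:
                g_of[d] = k
        ids = deme_ids if deme_ids is not None else list(g_of)
        return cls(list(ids), g_of)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"deme_id": self.deme_ids, "group": [self.group_of[d] for d in self.deme_ids]}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class AmovaResult:
    f_ct: float
    f_sc: float
    f_st: float
    variance_components: tuple  # (among groups, among demes within, within demes)
    p_values: dict = field(default_factory=dict)

    @property
    def total_variance(self) -> float:
        return float(sum(self.variance_components))


# ---------------------------------------------------------------------------


def _deme_cross_sums(t: HaplotypeTable) -> np.ndarray:
    """W[d1, d2] = sum of pairwise squared distances over ordered
    sequence pairs drawn from demes d1 and d2."""
    d2 = t.diff_matrix().astype(float)
    c = t.counts.astype(float)
    return c.T @ d2 @ c


def _amova_components(W: np.ndarray, sizes: np.ndarray, groups: list) -> tuple:
    """Variance components (sigma_a, sigma_b, sigma_c) from deme cross-sums.

    ``groups`` is a list of lists of deme indices.
    """
    sizes = np.asarray(sizes, dtype=float)
    N = sizes.sum()
    D = len(sizes)
    G = len(groups)
    ss_wp = sum(W[d, d] / 2.0 / sizes[d] for d in range(D) if sizes[d] > 0)
    t_g = []
    n_g = []
    for g in groups:
        idx = np.array(g)
        n_gg = sizes[idx].sum()
        n_g.append(n_gg)
        t_g.append(W[np.ix_(idx, idx)].sum() / 2.0 / n_gg)
    ss_total = W.sum() / 2.0 / N
    ss_ag = ss_total - sum(t_g)
    ss_ap = sum(t_g) - ss_wp

    df_wp = N - D
    df_ap = D - G
    df_ag = G - 1
    if df_ag < 1:
        raise ValueError("F_CT undefined for a single group")
    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0:
        sum_sq_within_g = sum(
            (sizes[np.array(g)] ** 2).sum() / n_gg for g, n_gg in zip(groups, n_g)
        )
        n_coef = (N - sum_sq_within_g) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n_coef
        n_p = (sum_sq_within_g - (sizes**2).sum() / N) / df_ag
        n_pp = (N - np.sum(np.array(n_g) ** 2) / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n_p * sigma_b) / n_pp
    else:
        # saturated partition: every deme its own group, two-level model
        sigma_b = 0.0
        n_c = (N - (sizes**2).sum() / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c) / n_c
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _fct(W, sizes, groups) -> float:
    a, b, c = _amova_components(W, sizes, groups)
    tot = a + b + c
    return a / tot if tot > 0 else 0.0


def amova(
    t: HaplotypeTable,
    partition: GroupingPartition,
    n_perm: int = 0,
    seed=None,
) -> AmovaResult:
    """Three-level AMOVA for a partition of demes into groups.

    Permutation p-values (when ``n_perm`` > 0): F_CT by permuting whole
    demes among groups, F_SC by permuting individuals among demes within
    their group.
    """
    if partition.K < 2:
        raise ValueError("F_CT undefined for K = 1")
    order = {d: i for i, d in enumerate(t.deme_ids)}
    groups = [[order[d] for d in g] for g in partition.groups()]
    W = _deme_cross_sums(t)
    sizes = t.deme_sizes()
    a, b, c = _amova_components(W, sizes, groups)
    tot = a + b + c
    f_ct = a / tot if tot > 0 else 0.0
    f_sc = b / (b + c) if (b + c) > 0 else 0.0
    f_st = (a + b) / tot if tot > 0 else 0.0
    res = AmovaResult(f_ct, f_sc, f_st, (a, b, c))
    if n_perm > 0:
        if seed is None:
            raise ValueError("seed is required for permutation p-values")
        rng = np.random.default_rng(seed)
        sizes_per_group = [len(g) for g in groups]
        all_demes = [d for g in groups for d in g]
        ge_ct = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_demes)
            pg, at = [], 0
            for s in sizes_per_group:
                pg.append(list(perm[at : at + s]))
                at += s
            if _fct(W, sizes, pg) >= f_ct - 1e-12:
                ge_ct += 1
        # F_SC: shuffle individuals among demes within each group
        ge_sc = 0
        seq_deme = np.repeat(np.arange(len(sizes)), sizes)
        seq_hap = np.concatenate(
            [np.repeat(np.arange(t.n_haplotypes), t.counts[:, j]) for j in range(len(sizes))]
        )
        d2 = t.diff_matrix().astype(float)
        for _ in range(n_perm):
            new_counts = np.zeros_like(t.counts)
            for g in groups:
                in_g = np.isin(seq_deme, g)
                haps = seq_hap[in_g].copy()
                rng.shuffle(haps)
                at = 0
                for d in g:
                    nd = int(sizes[d])
                    new_counts[:, d] = np.bincount(
                        haps[at : at + nd], minlength=t.n_haplotypes
                    )
                    at += nd
            Wp = new_counts.T.astype(float) @ d2 @ new_counts.astype(float)
            ap, bp, cp = _amova_components(Wp, sizes, groups)
            if (bp / (bp + cp) if (bp + cp) > 0 else 0.0) >= f_sc - 1e-12:
                ge_sc += 1
        res.p_values = {
            "f_ct": (ge_ct + 1) / (n_perm + 1),
            "f_sc": (ge_sc + 1) / (n_perm + 1),
        }
    return res


# ---------------------------------------------------------------------------
# contiguity graph


def build_contiguity_graph(m: SampleMetadata) -> nx.Graph:
    """Delaunay neighbourhood graph of deme coordinates.

    Collinear layouts fall back to a chain along the dominant axis;
    duplicated coordinates are deterministically jittered (with a
    warning) so the triangulation is defined.
    """
    coords = m.deme_coords()
    demes = list(coords.index)
    if len(demes) < 3:
        g = nx.Graph()
        g.add_nodes_from(demes)
        if len(demes) == 2:
            g.add_edge(demes[0], demes[1])
        return g
    xy = coords[["lon", "lat"]].to_numpy(float)
    if pd.DataFrame(xy).duplicated().any():
        warnings.warn("duplicate deme coordinates; applying deterministic jitter")
        for i, d in enumerate(sorted(range(len(demes)), key=lambda i: demes[i])):
            xy[d] = xy[d] + 1e-6 * (i + 1)
    g = nx.Graph()
    g.add_nodes_from(demes)
    try:
        tri = Delaunay(xy)
        for simplex in tri.simplices:
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(demes[simplex[i]], demes[simplex[j]])
    except QhullError:
        # collinear: chain by projection on the principal axis
        v = xy - xy.mean(axis=0)
        axis = np.linalg.svd(v, full_matrices=False)[2][0]
        order = np.argsort(v @ axis)
        for a, b in zip(order[:-1], order[1:]):
            g.add_edge(demes[a], demes[b])
    return g


# ---------------------------------------------------------------------------
# SAMOVA


def _connected(sub_nodes: set, adj: dict) -> bool:
    it = iter(sub_nodes)
    start = next(it)
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in sub_nodes and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(sub_nodes)


def _random_contiguous_partition(demes, adj, K, rng) -> dict:
    seeds = list(rng.choice(len(demes), size=K, replace=False))
    assign = {demes[s]: k for k, s in enumerate(seeds)}
    frontier = list(assign)
    while len(assign) < len(demes):
        grew = False
        order = rng.permutation(len(frontier))
        for i in order:
            u = frontier[i]
            unassigned = [v for v in adj[u] if v not in assign]
            if unassigned:
                v = unassigned[int(rng.integers(len(unassigned)))]
                assign[v] = assign[u]
                frontier.append(v)
                grew = True
                break
        if not grew:
            # graph disconnected relative to seeds; restart
            return _random_contiguous_partition(demes, adj, K, rng)
    return assign


@dataclass
class SamovaRun:
    f_ct: float
    partition: GroupingPartition
    n_accepted: int
    n_proposed: int


def samova(
    t: HaplotypeTable,
    graph: nx.Graph,
    K: int,
    n_runs: int = 100,
    seed=None,
    cooling: float = 0.9,
    proposals_per_temp: int = 100,
    patience: int = 50,
) -> tuple:
    """Simulated-annealing search for the contiguous K-partition of demes
    maximizing F_CT.

    Returns ``(best_partition, best_amova, trace)`` where trace is one
    :class:`SamovaRun` per independent annealing chain.  The annealing
    schedule is geometric (T <- cooling * T) from a starting temperature
    calibrated so that about half of early uphill/downhill proposals are
    accepted; a chain stops after ``patience`` temperatures without
    improving its best F_CT.
    """
    if seed is None:
        raise ValueError("seed is required")
    demes = list(t.deme_ids)
    if not set(graph.nodes) >= set(demes):
        raise ValueError("contiguity graph is missing demes")
    if K > len(demes) or K < 2:
        raise ValueError("need 2 <= K <= number of demes")
    if not nx.is_connected(graph.subgraph(demes)):
        raise ValueError("contiguity graph is disconnected over the demes")
    adj = {d: [v for v in graph.neighbors(d) if v in set(demes)] for d in demes}
    W = _deme_cross_sums(t)
    sizes = t.deme_sizes()
    order = {d: i for i, d in enumerate(demes)}

    def score(assign: dict) -> float:
        groups: list = [[] for _ in range(K)]
        for d in demes:
            groups[assign[d]].append(order[d])
        return _fct(W, sizes, groups)

    def proposals(assign):
        """Moves (deme, new_group) that keep all groups contiguous, non-empty."""
        out = []
        members: list = [set() for _ in range(K)]
        for d in demes:
            members[assign[d]].add(d)
        for d in demes:
            g = assign[d]
            if len(members[g]) == 1:
                continue
            rest = members[g] - {d}
            if not _connected(rest, adj):
                continue
            for gn in {assign[v] for v in adj[d]} - {g}:
                out.append((d, gn))
        return out

    rng = np.random.default_rng(seed)
    best_f, best_assign, best_canon = -np.inf, None, None
    trace = []
    for _ in range(n_runs):
        assign = _random_contiguous_partition(demes, adj, K, rng)
        f = score(assign)
        run_best_f, run_best = f, dict(assign)
        # calibrate T0 from the spread of early proposal deltas
        deltas = []
        for d, gn in proposals(assign)[:40]:
            trial = dict(assign)
            trial[d] = gn
            deltas.append(abs(score(trial) - f))
        t0 = max(np.median(deltas), 1e-6) / np.log(2.0) if deltas else 1e-3
        T = t0
        stale = 0
        n_acc = n_prop = 0
        while stale < patience:
            improved = False
            for _ in range(proposals_per_temp):
                moves = proposals(assign)
                if not moves:
                    break
                d, gn = moves[int(rng.integers(len(moves)))]
                trial = dict(assign)
                trial[d] = gn
                f_new = score(trial)
                n_prop += 1
                if f_new > f or rng.random() < np.exp((f_new - f) / T):
                    assign, f = trial, f_new
                    n_acc += 1
                    if f > run_best_f + 1e-12:
                        run_best_f, run_best = f, dict(assign)
                        improved = True
            T *= cooling
            stale = 0 if improved else stale + 1
        part = GroupingPartition(demes, {d: g for d, g in run_best.items()})
        trace.append(SamovaRun(run_best_f, part, n_acc, n_prop))
        canon = part.canonical()
        if run_best_f > best_f + 1e-12 or (
            abs(run_best_f - best_f) <= 1e-12 and (best_canon is None or canon < best_canon)
        ):
            best_f, best_assign, best_canon = run_best_f, run_best, canon
    # renumber groups canonically for deterministic reporting
    canon_map: dict = {}
    g_of = {}
    for d in demes:
        g = best_assign[d]
        if g not in canon_map:
            canon_map[g] = len(canon_map)
        g_of[d] = canon_map[g]
    best_part = GroupingPartition(demes, g_of)
    return best_part, amova(t, best_part), trace


def exhaustive_best_bipartition(t: HaplotypeTable, graph: nx.Graph) -> tuple:
    """Exact best contiguous 2-group partition by subset enumeration.

    Feasible up to ~15 demes; used as an oracle for the annealer.
    """
    demes = list(t.deme_ids)
    D = len(demes)
    adj = {d: set(graph.neighbors(d)) & set(demes) for d in demes}
    W = _deme_cross_sums(t)
    sizes = t.deme_sizes()
    order = {d: i for i, d in enumerate(demes)}
    best = (-np.inf, None)
    for mask in range(1, (1 << D) - 1):
        if not mask & 1:
            continue  # fix deme 0 in group 0 to halve the enumeration
        g0 = {demes[i] for i in range(D) if mask >> i & 1}
        g1 = set(demes) - g0
        if not (_connected(g0, adj) and _connected(g1, adj)):
            continue
        f = _fct(W, sizes, [[order[d] for d in g0], [order[d] for d in g1]])
        if f > best[0]:
            best = (f, GroupingPartition(demes, {d: int(d in g1) for d in demes}))
    return best[1], best[0]
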