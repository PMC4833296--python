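"""Coalescent simulation engine.

Two entry points are provided:

* :func:`neutral_genealogy` — a single panmictic population of constant
  size, with time measured in units of N generations (coalescent units).
  Used for neutrality-test null distributions and calibration.
* :func:`scenario_genealogy` — an event-driven structured coalescent over
  several populations with piecewise-constant (haploid) effective sizes
  and population merges (backward-in-time splits), with time measured in
  generations.  Used by the ABC scenario simulator.

Mutations can be dropped either conditioned on a fixed number of
segregating sites (infinite-sites, the DnaSP-style null) or as a Poisson
process on branches with a finite-sites substitution model with a
transition/transversion bias.

All population sizes are haploid effective sizes: the data this package
models are single-locus mitochondrial sequences, so a "population of size
N" contributes pairwise coalescence at rate 1/N per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.array(["A", "C", "G", "T"])
# transition partner of A,C,G,T (indices 0..3): A<->G, C<->T
_TS_PARTNER = np.array([2, 3, 0, 1])
# the two transversion partners of each base
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass
class Genealogy:
    """A realized coalescent tree.

    Nodes 0..n-1 are leaves (time 0 unless serially sampled, which we
    never are here); internal nodes follow in coalescence order.  The
    root's parent is -1.  ``leafmask[v]`` is an integer bitmask of the
    leaves below ``v`` (bit i set iff leaf i is a descendant).
    """

    n: int
    parent: np.ndarray           # (2n-1,) int
    time: np.ndarray             # (2n-1,) float, node ages
    leafmask: list               # (2n-1,) python ints
    leaf_pop: np.ndarray | None = None   # (n,) object, sampling population

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def leaf_counts(self) -> np.ndarray:
        return np.array([bin(m).count("1") for m in self.leafmask])

    def children(self) -> list:
        ch: list = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                ch[p].append(v)
        return ch


def neutral_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Kingman coalescent for ``n`` lineages, constant size, coalescent units."""
    if n < 2:
        raise ValueError("need at least two lineages")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leafmask = [1 << i for i in range(n)] + [0] * (n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = rng.integers(k)
        a = active.pop(i)
        j = rng.integers(k - 1)
        b = active.pop(j)
        parent[a] = parent[b] = nxt
        time[nxt] = t
        leafmask[nxt] = leafmask[a] | leafmask[b]
        active.append(nxt)
        nxt += 1
    return Genealogy(n=n, parent=parent, time=time, leafmask=leafmask)


def scenario_genealogy(
    samples: dict,
    size_epochs: dict,
    merges: list,
    rng: np.random.Generator,
) -> Genealogy:
    """Structured coalescent with population merges and size changes.

    Parameters
    ----------
    samples
        ``{pop: n_sampled}``; leaves are ordered by population in dict order.
    size_epochs
        ``{pop: [(t_start, N), ...]}`` piecewise-constant haploid sizes,
        breakpoints ascending, first breakpoint at 0.
    merges
        ``[(t, child, parent), ...]`` — backward in time, at ``t`` all
        lineages of ``child`` move into ``parent``.
    """
    pops = list(samples)
    n = int(sum(samples.values()))
    if n < 2:
        raise ValueError("need at least two sampled lineages")
    for pop, eps in size_epochs.items():
        for _, N in eps:
            if N <= 0:
                raise ValueError(f"population size must be positive (pop {pop})")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leafmask = [1 << i for i in range(n)] + [0] * (n - 1)
    leaf_pop = np.empty(n, dtype=object)

    lineages: dict = {p: [] for p in pops}
    i = 0
    for p, np_ in samples.items():
        for _ in range(int(np_)):
            leaf_pop[i] = p
            lineages[p].append(i)
            i += 1

    # event list: merges and size breakpoints, time-ascending
    events = [(float(t), "merge", c, par) for (t, c, par) in merges]
    for p, eps in size_epochs.items():
        for t, N in eps:
            if t > 0:
                events.append((float(t), "size", p, N))
    events.sort(key=lambda e: e[0])

    def cur_size(p: str, t: float) -> float:
        N = None
        for t0, N0 in size_epochs[p]:
            if t0 <= t + 1e-12:
                N = N0
        if N is None:
            raise ValueError(f"no size epoch covers time {t} for pop {p}")
        return float(N)

    t = 0.0
    nxt = n
    ev_i = 0
    while True:
        k_tot = sum(len(v) for v in lineages.values())
        if k_tot <= 1:
            break
        # total coalescence rate per generation
        rates = {}
        for p, lin in lineages.items():
            k = len(lin)
            if k >= 2:
                rates[p] = k * (k - 1) / 2.0 / cur_size(p, t)
        tot = sum(rates.values())
        t_next_ev = events[ev_i][0] if ev_i < len(events) else np.inf
        dt = rng.exponential(1.0 / tot) if tot > 0 else np.inf
        if t + dt < t_next_ev:
            t = t + dt
            # choose population proportional to rate
            u = rng.random() * tot
            acc = 0.0
            for p, r in rates.items():
                acc += r
                if u <= acc:
                    break
            lin = lineages[p]
            i = rng.integers(len(lin))
            a = lin.pop(i)
            j = rng.integers(len(lin))
            b = lin.pop(j)
            parent[a] = parent[b] = nxt
            time[nxt] = t
            leafmask[nxt] = leafmask[a] | leafmask[b]
            lin.append(nxt)
            nxt += 1
        else:
            if not np.isfinite(t_next_ev):
                raise RuntimeError("coalescent stalled: no rate and no events left")
            t = t_next_ev
            _, kind, x, y = events[ev_i]
            ev_i += 1
            if kind == "merge":
                lineages.setdefault(y, []).extend(lineages.pop(x, []))
            # size events need no action: cur_size reads epochs by time
    return Genealogy(
        n=n, parent=parent, time=time, leafmask=leafmask, leaf_pop=leaf_pop
    )


# ---------------------------------------------------------------------------
# mutation placement and branch-level summaries


def mutations_fixed_s(g: Genealogy, S: int, rng: np.random.Generator) -> np.ndarray:
    """Drop exactly ``S`` infinite-sites mutations, multinomially by length."""
    bl = g.branch_lengths()
    tot = bl.sum()
    if tot <= 0:
        raise ValueError("degenerate genealogy with zero length")
    return rng.multinomial(S, bl / tot)


def mutations_poisson(
    g: Genealogy, rate_per_unit: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson mutations per branch at ``rate_per_unit`` per time unit."""
    bl = g.branch_lengths()
    return rng.poisson(rate_per_unit * bl)


@dataclass
class BranchSummaries:
    """Summary statistics computed directly from mutation-labelled branches."""

    n: int
    S: int
    k_mean: float
    NH: int
    U: np.ndarray  # per-leaf singleton-mutation loads


def branch_summaries(
    g: Genealogy, muts: np.ndarray, rng: np.random.Generator
) -> BranchSummaries:
    """S, mean pairwise differences, haplotype count and singleton loads.

    Assumes infinite sites (every mutation its own site), which is exact
    for the fixed-S null machinery.  Haplotypes are identified by hashing
    the set of mutated branches on each leaf's root path.
    """
    n = g.n
    counts = g.leaf_counts()
    npairs = n * (n - 1) / 2.0
    k_mean = float((muts * counts * (n - counts)).sum() / npairs)
    S = int(muts.sum())

    # haplotype hashes: random label per mutated branch, summed down paths
    labels = np.zeros(g.n_nodes, dtype=np.uint64)
    mutated = np.nonzero(muts)[0]
    labels[mutated] = rng.integers(0, 2**63, size=len(mutated), dtype=np.uint64)
    # also separate equal branches carrying different numbers of mutations
    path = np.zeros(g.n_nodes, dtype=np.uint64)
    order = np.argsort(-g.time)  # root first
    with np.errstate(over="ignore"):  # modular uint64 hashing wraps by design
        for v in order:
            p = g.parent[v]
            if p >= 0:
                path[v] = path[p] + labels[v] * np.uint64(muts[v])
    NH = len(set(path[:n].tolist()))

    U = np.zeros(n)
    for v in mutated:
        c = counts[v]
        if c == 1:
            U[g.leafmask[v].bit_length() - 1] += muts[v]
        elif c == n - 1:
            full = (1 << n) - 1
            U[(full ^ g.leafmask[v]).bit_length() - 1] += muts[v]
    return BranchSummaries(n=n, S=S, k_mean=k_mean, NH=NH, U=U)


# ---------------------------------------------------------------------------
# finite-sites sequence generation (for ABC and synthetic datasets)


def sequence_matrix(
    g: Genealogy,
    mu_per_site: float,
    L: int,
    rng: np.random.Generator,
    kappa: float = 4.75,
) -> tuple:
    """Evolve sequences down the tree under a finite-sites model.

    Returns ``(states, positions)`` where ``states`` is an (n, S*) array of
    base indices at the S* sites hit by at least one mutation (columns in
    ascending position order; multiple hits at one site are allowed and
    applied in time order), and ``positions`` the 0-based site indices.
    Transitions occur with probability kappa/(kappa+1) per mutation.
    """
    bl = g.branch_lengths()
    n_mut = rng.poisson(mu_per_site * L * bl.sum())
    if n_mut == 0:
        return np.zeros((g.n, 0), dtype=np.int8), np.array([], dtype=np.int64)
    branch = rng.choice(g.n_nodes, size=n_mut, p=bl / bl.sum())
    sites = rng.integers(0, L, size=n_mut)
    is_ts = rng.random(n_mut) < kappa / (kappa + 1.0)
    tv_pick = rng.integers(0, 2, size=n_mut)

    positions, col = np.unique(sites, return_inverse=True)
    S_star = len(positions)
    root_state = rng.integers(0, 4, size=S_star).astype(np.int8)

    # per-branch mutation lists (site column, ts flag, tv pick)
    per_branch: dict = {}
    for m in range(n_mut):
        per_branch.setdefault(int(branch[m]), []).append(m)

    states = np.empty((g.n_nodes, S_star), dtype=np.int8)
    order = np.argsort(-g.time)  # root first
    root = order[0]
    states[root] = root_state
    for v in order:
        p = g.parent[v]
        if p >= 0:
            row = states[p].copy()
            for m in per_branch.get(int(v), ()):
                c = col[m]
                b = row[c]
                row[c] = _TS_PARTNER[b] if is_ts[m] else _TV_PARTNERS[b][tv_pick[m]]
            states[v] = row
    return states[: g.n], positions


def expansion_genealogy(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> Genealogy:
    """Coalescent under the sudden-expansion model, in mutational time units.

    Time is measured in units of 1/(2u) generations, so that a pair of
    lineages coalescing at time x accumulates Poisson(x) differences and
    the pairwise coalescence rate at time x is 1/theta(x), with theta(x)
    = theta1 for x < tau (post-expansion size) and theta0 beyond.  Branch
    lengths are therefore directly on the mutational scale; drop mutations
    with :func:`mutations_poisson` at rate 1/2 per branch-length unit.
    """
    if theta1 <= 0:
        raise ValueError("theta1 must be positive")
    epochs = [(0.0, theta1)]
    if theta0 != theta1:
        # theta0 == 0 -> everything remaining coalesces instantly at tau
        epochs.append((float(tau), max(theta0, 1e-9)))
    return scenario_genealogy(
        {"pop": n}, {"pop": epochs}, [], rng
    )
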