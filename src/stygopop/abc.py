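"""Approximate Bayesian computation for phylogeographic scenario choice.

Competing demographic scenarios (fragmentation versus stepping-stone
dispersal, with founder bottlenecks after every dispersal event) are
compared by simulating mtDNA samples under parameter draws from the
priors, summarizing each simulated dataset with the same statistics as
the observed data (per-group number of haplotypes, segregating sites,
mean and variance of pairwise differences; optionally pairwise Phi_ST
and between-group mean differences), and estimating posterior scenario
probabilities both by the rejection proportion among the retained
nearest simulations and by weighted multinomial logistic regression of
the scenario indicator on the summaries (Beaumont's regression
adjustment for model choice).

Population sizes are haploid effective sizes (single-locus mtDNA).
Scenario sets mirror a three-region system (P: western region, H:
central region, M: eastern region) and two two-region subsystems.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import sim, stats
from .haplotypes import HaplotypeTable

BASES = "ACGT"


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class DemographicScenario:
    """Event-list description of one demographic history.

    events: time-ordered (backward) list of dicts; kinds:
      {"kind": "split", "child": pop, "parent": pop, "time": t_key}
      {"kind": "bottleneck", "pop": pop, "nf": Nf_key, "bd": Bd_key,
       "time": t_key}   # size nf during [t - bd, t), i.e. just after the
                        # forward-time founding at t
    size_symbols maps every population (sampled or ancestral) to the
    name of its N parameter; ``ancestral_size`` names the stem size that
    applies in the root population beyond the last split.
    """

    scenario_id: str
    pops: list
    events: list
    size_symbols: dict
    ancestral_size: str = "N_anc"
    description: str = ""

    def time_keys(self) -> list:
        return sorted({e["time"] for e in self.events})

    def build(self, params: dict) -> tuple:
        """(size_epochs, merges) in the form the simulator expects."""
        epochs = {p: [(0.0, float(params[s]))] for p, s in self.size_symbols.items()}
        merges = []
        child_of: dict = {}
        for e in self.events:
            t = float(params[e["time"]])
            if t <= 0:
                raise ValueError("event times must be strictly positive")
            if e["kind"] == "split":
                merges.append((t, e["child"], e["parent"]))
                child_of[e["child"]] = t
            elif e["kind"] == "bottleneck":
                nf, bd = float(params[e["nf"]]), float(params[e["bd"]])
                start = max(t - bd, 1e-9)
                epochs[e["pop"]].append((start, nf))
            else:
                raise ValueError(f"unknown event kind {e['kind']!r}")
        merges.sort(key=lambda m: m[0])
        # sanity: every sampled pop must eventually reach the root
        pops_alive = set(self.pops)
        for t, c, p in merges:
            if c in pops_alive:
                pops_alive.discard(c)
                pops_alive.add(p)
        if len(pops_alive) != 1:
            raise ValueError(
                f"scenario {self.scenario_id}: sampled pops do not coalesce "
                f"to a single root (left: {sorted(pops_alive)})"
            )
        root = pops_alive.pop()
        t_last = merges[-1][0] if merges else 0.0
        epochs.setdefault(root, [(0.0, float(params[self.ancestral_size]))])
        epochs[root].append((t_last, float(params[self.ancestral_size])))
        for p in epochs:
            epochs[p].sort(key=lambda e: e[0])
        return epochs, merges


def _disperse(pop, source, tkey):
    """A forward-time dispersal: backward merge plus founder bottleneck."""
    return [
        {"kind": "bottleneck", "pop": pop, "nf": f"Nf_{pop}", "bd": f"Bd_{pop}",
         "time": tkey},
        {"kind": "split", "child": pop, "parent": source, "time": tkey},
    ]


def load_scenarios(config: str = "major") -> list:
    """Built-in scenario sets.

    ``"major"``: three regions P (west), H (centre), M (east) —
      1: ancestral fragmentation into H and M at t1, dispersal H->P at t0;
      2: H ancestral, dispersal H->M at t1 and H->P at t0;
      3: M ancestral, stepping-stone dispersal M->H at t1, H->P at t0.
    ``"matanzas"``: two eastern groups D, E from a central ancestral —
      4 fragmentation, 5 dispersal D->E, 6 dispersal E->D (at t0).
    ``"pinar"``: two western groups A, B —
      7 fragmentation, 8 dispersal B->A (at t0).
    """
    if config == "major":
        return [
            DemographicScenario(
                "1", ["P", "H", "M"],
                _disperse("P", "H", "t0")
                + [{"kind": "split", "child": "H", "parent": "ANC", "time": "t1"},
                   {"kind": "split", "child": "M", "parent": "ANC", "time": "t1"}],
                {"P": "N_P", "H": "N_H", "M": "N_M", "ANC": "N_anc"},
                description="fragmentation H-M, then dispersal H->P",
            ),
            DemographicScenario(
                "2", ["P", "H", "M"],
                _disperse("M", "H", "t1") + _disperse("P", "H", "t0"),
                {"P": "N_P", "H": "N_H", "M": "N_M"},
                description="H origin, dispersal east then west",
            ),
            DemographicScenario(
                "3", ["P", "H", "M"],
                _disperse("H", "M", "t1") + _disperse("P", "H", "t0"),
                {"P": "N_P", "H": "N_H", "M": "N_M"},
                description="M origin, stepping-stone dispersal east to west",
            ),
        ]
    if config == "matanzas":
        return [
            DemographicScenario(
                "4", ["D", "E"],
                [{"kind": "split", "child": "D", "parent": "ANC", "time": "t0"},
                 {"kind": "split", "child": "E", "parent": "ANC", "time": "t0"}],
                {"D": "N_D", "E": "N_E", "ANC": "N_anc"},
                description="fragmentation D-E",
            ),
            DemographicScenario(
                "5", ["D", "E"], _disperse("E", "D", "t0"),
                {"D": "N_D", "E": "N_E"},
                description="D origin, dispersal to E",
            ),
            DemographicScenario(
                "6", ["D", "E"], _disperse("D", "E", "t0"),
                {"D": "N_D", "E": "N_E"},
                description="E origin, dispersal to D",
            ),
        ]
    if config == "pinar":
        return [
            DemographicScenario(
                "7", ["A", "B"],
                [{"kind": "split", "child": "A", "parent": "ANC", "time": "t0"},
                 {"kind": "split", "child": "B", "parent": "ANC", "time": "t0"}],
                {"A": "N_A", "B": "N_B", "ANC": "N_anc"},
                description="fragmentation A-B",
            ),
            DemographicScenario(
                "8", ["A", "B"], _disperse("A", "B", "t0"),
                {"A": "N_A", "B": "N_B"},
                description="B origin, dispersal to A",
            ),
        ]
    raise ValueError(f"unknown scenario set {config!r}")


DEFAULT_SAMPLE_SIZES = {
    "major": {"P": 23, "H": 29, "M": 38},
    "matanzas": {"D": 23, "E": 15},
    "pinar": {"A": 6, "B": 17},
}


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorSpec:
    """Independent per-parameter priors with ordering constraints.

    distributions: name -> ("uniform"|"loguniform", low, high)
    constraints: list of (a, ">", b) with a, b parameter names; draws are
    rejected and redrawn until all hold.
    """

    distributions: dict
    constraints: list = field(default_factory=list)

    def __post_init__(self):
        for name, (kind, lo, hi) in self.distributions.items():
            if kind not in ("uniform", "loguniform"):
                raise ValueError(f"{name}: unknown distribution {kind!r}")
            if not (0 <= lo <= hi) or not np.isfinite(hi):
                raise ValueError(f"{name}: bounds must satisfy 0 <= low <= high")
            if kind == "loguniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform needs a positive lower bound")

    def hash(self) -> str:
        blob = json.dumps(
            {"d": self.distributions, "c": self.constraints}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def sample(self, rng: np.random.Generator, max_tries: int = 1_000_000) -> dict:
        for _ in range(max_tries):
            draw = {}
            for name, (kind, lo, hi) in self.distributions.items():
                if kind == "uniform":
                    draw[name] = rng.uniform(lo, hi)
                else:
                    draw[name] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            if all(draw[a] > draw[b] for a, _, b in self.constraints):
                return draw
        raise RuntimeError("prior constraints look infeasible (rejection limit hit)")


def default_priors(scenarios: list) -> PriorSpec:
    """Default prior box for a scenario set (haploid N, generations, per-site mu)."""
    dist: dict = {"mu": ("loguniform", 1e-8, 1e-7)}
    constraints: list = []
    tkeys: set = set()
    sizes: set = set()
    for sc in scenarios:
        tkeys |= set(sc.time_keys())
        sizes |= set(sc.size_symbols.values()) | {sc.ancestral_size}
        for e in sc.events:
            if e["kind"] == "bottleneck":
                dist[e["nf"]] = ("uniform", 2, 100)
                dist[e["bd"]] = ("uniform", 1, 50)
    for s in sizes:
        dist[s] = ("loguniform", 1e2, 1e5)
    for t in tkeys:
        dist[t] = ("uniform", 1e2, 1e5)
    for hi, lo in zip(sorted(tkeys, reverse=True)[:-1], sorted(tkeys, reverse=True)[1:]):
        constraints.append((hi, ">", lo))
    # size ordering: ancestral largest; centre > east > west where present
    if "N_anc" in sizes:
        for s in sorted(sizes - {"N_anc"}):
            constraints.append(("N_anc", ">", s))
    for a, b in (("N_H", "N_M"), ("N_M", "N_P"), ("N_E", "N_D"), ("N_H", "N_P")):
        if a in sizes and b in sizes:
            constraints.append((a, ">", b))
    return PriorSpec(dist, constraints)


# ---------------------------------------------------------------------------
# simulation and summaries


def simulate_coalescent(
    scenario: DemographicScenario,
    params: dict,
    sample_sizes: dict,
    L: int = 1217,
    rng: np.random.Generator | None = None,
    seed=None,
    kappa: float = 4.75,
) -> HaplotypeTable:
    """Simulate one mtDNA sample under a scenario and collapse to haplotypes."""
    if rng is None:
        rng = np.random.default_rng(seed)
    for p, n in sample_sizes.items():
        if n <= 0:
            raise ValueError(f"sample size for {p} must be positive")
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    epochs, merges = scenario.build(params)
    g = sim.scenario_genealogy(sample_sizes, epochs, merges, rng)
    states, positions = sim.sequence_matrix(g, float(params["mu"]), L, rng, kappa)
    return _states_to_table(states, positions, g.leaf_pop, list(sample_sizes), L)


def _states_to_table(states, positions, leaf_pop, pops, L) -> HaplotypeTable:
    # keep only sites actually variable among the sampled leaves
    if states.shape[1]:
        keep = np.array([len(set(states[:, j])) > 1 for j in range(states.shape[1])])
        states = states[:, keep]
        positions = positions[keep]
    seqs = ["".join(BASES[b] for b in row) for row in states]
    hap_index: dict = {}
    haps: list = []
    counts_rows: list = []
    for i, s in enumerate(seqs):
        if s not in hap_index:
            hap_index[s] = len(haps)
            haps.append(s)
            counts_rows.append(np.zeros(len(pops), dtype=int))
        counts_rows[hap_index[s]][pops.index(leaf_pop[i])] += 1
    if not haps:  # monomorphic sample
        haps = [""]
        counts_rows = [np.zeros(len(pops), dtype=int)]
        for i in range(len(seqs)):
            counts_rows[0][pops.index(leaf_pop[i])] += 1
    return HaplotypeTable(
        haps, np.array(counts_rows), list(pops), L, [int(p) for p in positions]
    )


def summary_labels(groups: list, include_pairwise: bool = False) -> list:
    labels = []
    for g in groups:
        labels += [f"NH_{g}", f"S_{g}", f"kmean_{g}", f"kvar_{g}"]
    if include_pairwise:
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                labels += [f"fst_{a}_{b}", f"kbetween_{a}_{b}"]
    return labels


def summarize(
    t: HaplotypeTable, grouping: dict | None = None, include_pairwise: bool = False
) -> np.ndarray:
    """Canonical summary-statistic vector of a haplotype table.

    grouping maps group -> list of demes (defaults to one group per deme).
    Per group: NH, S, mean pairwise differences, variance of pairwise
    differences (0 for n < 2 pairs); optional per pair: Phi_ST and mean
    between-group differences (undefined Phi_ST reported as 0).
    """
    if grouping is None:
        grouping = {d: [d] for d in t.deme_ids}
    vec = []
    merged = t.merge_demes(
        {d: g for g, demes in grouping.items() for d in demes}
    )
    for g in grouping:
        if merged.counts[:, merged.deme_ids.index(g)].sum() == 0:
            raise ValueError(f"empty group {g!r}")
        sub = merged.subset([g])
        pooled = sub.counts.sum(axis=1)
        NH = int((pooled > 0).sum())
        S = stats.segregating_sites(sub)
        if sub.n >= 2:
            k_mean, k_var, _ = stats.pairwise_difference_moments(sub)
        else:
            k_mean = k_var = 0.0
        vec += [NH, S, k_mean, k_var]
    if include_pairwise:
        d = merged.diff_matrix().astype(float)
        groups = list(grouping)
        for i, a in enumerate(groups):
            ca = merged.counts[:, merged.deme_ids.index(a)].astype(float)
            for b in groups[i + 1:]:
                cb = merged.counts[:, merged.deme_ids.index(b)].astype(float)
                phi = stats._phi_st_two_groups(d, ca, cb)
                vec.append(0.0 if not np.isfinite(phi) else phi)
                vec.append(float(ca @ d @ cb / (ca.sum() * cb.sum())))
    return np.array(vec, dtype=float)


# ---------------------------------------------------------------------------
# reference table and model choice


@dataclass
class ReferenceTable:
    frame: pd.DataFrame          # scenario + parameter columns + summary columns
    summary_cols: list
    meta: dict = field(default_factory=dict)

    def summaries(self) -> np.ndarray:
        return self.frame[self.summary_cols].to_numpy(float)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# meta={json.dumps(self.meta, sort_keys=True)}\n")
            fh.write(f"# summary_cols={','.join(self.summary_cols)}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ReferenceTable":
        meta, cols = {}, []
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                if key == "meta":
                    meta = json.loads(val)
                elif key == "summary_cols":
                    cols = val.split(",")
        frame = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"scenario": str})
        return cls(frame, cols, meta)


def build_reference_table(
    scenarios: list,
    priors: PriorSpec,
    n_sims_per_scenario: int,
    sample_sizes: dict,
    L: int = 1217,
    seed=None,
    include_pairwise: bool = False,
    kappa: float = 4.75,
) -> ReferenceTable:
    """Prior-predictive reference table for ABC model choice.

    Every row is seeded independently from (seed, scenario index, row
    index), so the table is reproducible regardless of how the work is
    chunked or parallelized.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_sims_per_scenario < 1:
        raise ValueError("need at least one simulation per scenario")
    groups = list(sample_sizes)
    cols = summary_labels(groups, include_pairwise)
    rows = []
    for si, sc in enumerate(scenarios):
        for r in range(n_sims_per_scenario):
            rng = np.random.default_rng([int(seed), si, r])
            params = priors.sample(rng)
            t = simulate_coalescent(sc, params, sample_sizes, L, rng=rng, kappa=kappa)
            vec = summarize(t, {g: [g] for g in groups}, include_pairwise)
            rows.append({"scenario": sc.scenario_id, **params,
                         **dict(zip(cols, vec))})
    frame = pd.DataFrame(rows)
    meta = {
        "seed": int(seed),
        "n_sims_per_scenario": n_sims_per_scenario,
        "sample_sizes": sample_sizes,
        "L": L,
        "prior_hash": priors.hash(),
        "include_pairwise": include_pairwise,
    }
    return ReferenceTable(frame, cols, meta)


@dataclass
class PosteriorResult:
    scenario_ids: list
    logistic: dict            # scenario -> posterior probability
    rejection: dict           # scenario -> retained proportion
    n_retained: int
    degenerate: bool = False

    def best(self) -> str:
        return max(self.logistic, key=self.logistic.get)


def model_choice(
    ref: ReferenceTable,
    observed: np.ndarray,
    retain_frac: float = 0.10,
) -> PosteriorResult:
    """Scenario posterior probabilities by rejection + logistic regression.

    Summaries are standardized by the reference-table spread; the
    ``retain_frac`` simulations closest to the observed vector (Euclidean
    distance) are kept; the multinomial logistic estimate regresses the
    scenario indicator on the summaries with Epanechnikov distance
    weights and is evaluated at the observed point.
    """
    X = ref.summaries()
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (X.shape[1],):
        raise ValueError("observed summary dimension does not match table")
    y = ref.frame["scenario"].to_numpy()
    ids = sorted(set(y), key=lambda s: (len(s), s))
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - X.mean(axis=0)) / scale
    z_obs = (observed - X.mean(axis=0)) / scale
    dist = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(retain_frac * len(dist))), len(ids) + 1)
    keep = np.argsort(dist, kind="stable")[:n_keep]
    yk = y[keep]
    rejection = {s: float((yk == s).mean()) for s in ids}
    if len(set(yk)) < 2:
        only = yk[0]
        return PosteriorResult(
            ids,
            {s: float(s == only) for s in ids},
            rejection,
            n_keep,
            degenerate=True,
        )
    dmax = dist[keep].max()
    if dmax > 0:
        w = 1.0 - (dist[keep] / (dmax * (1 + 1e-9))) ** 2
    else:  # observed indistinguishable from every retained row
        w = np.ones(len(keep))
    clf = LogisticRegression(C=100.0, max_iter=5000)
    clf.fit(Z[keep], yk, sample_weight=w)
    probs = clf.predict_proba(z_obs[None, :])[0]
    logistic = {s: 0.0 for s in ids}
    for cls, p in zip(clf.classes_, probs):
        logistic[cls] = float(p)
    return PosteriorResult(ids, logistic, rejection, n_keep)


def scenario_recovery(
    scenario_set: str = "major",
    n_ref_per_scenario: int = 3000,
    n_test_per_scenario: int = 34,
    seed=1,
    retain_frac: float = 0.10,
    L: int = 1217,
) -> tuple:
    """Self-recovery experiment: simulate pseudo-observed datasets under
    each scenario and check that the generating scenario attains the
    maximum logistic posterior.  Returns (fraction recovered, confusion
    DataFrame)."""
    scenarios = load_scenarios(scenario_set)
    sizes = DEFAULT_SAMPLE_SIZES[scenario_set]
    priors = default_priors(scenarios)
    ref = build_reference_table(
        scenarios, priors, n_ref_per_scenario, sizes, L=L, seed=seed
    )
    ids = [sc.scenario_id for sc in scenarios]
    confusion = pd.DataFrame(0, index=ids, columns=ids)
    hits = total = 0
    for si, sc in enumerate(scenarios):
        for r in range(n_test_per_scenario):
            rng = np.random.default_rng([int(seed) + 7_777_777, si, r])
            params = priors.sample(rng)
            t = simulate_coalescent(sc, params, sizes, L, rng=rng)
            obs = summarize(t, {g: [g] for g in sizes})
            res = model_choice(ref, obs, retain_frac)
            confusion.loc[sc.scenario_id, res.best()] += 1
            hits += res.best() == sc.scenario_id
            total += 1
    return hits / total, confusion
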