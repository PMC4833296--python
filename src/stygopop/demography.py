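"""Demographic inference from mismatch distributions and neutrality tests.

The sudden-expansion model: a population at mutation-scaled size theta0
grew instantaneously to theta1 at a time tau before the present, tau
measured in units of 1/(2u) generations (mutational time).  The
expected distribution of pairwise differences under this history is
obtained from the pair-coalescence integral with piecewise-constant
theta, which reduces to

    F_i = Geo_i(theta1) * P(i+1, tau*(theta1+1)/theta1)
        + exp(-tau/theta1) * sum_m Pois_{i-m}(tau) * Geo_m(theta0)

with Geo_i(t) = t^i/(t+1)^(i+1), Pois the Poisson pmf and P the lower
regularized incomplete gamma function — the classic sudden-expansion
mismatch distribution.  Goodness of fit uses the sum of squared
deviations (SSD) with a parametric coalescent bootstrap; Tajima's D,
Fu's Fs and R2 get one-tailed p-values (lower tail, the direction of
demographic expansion) from standard neutral coalescent simulations
conditioned on the observed number of segregating sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import poisson

from . import sim
from .haplotypes import HaplotypeTable
from .stats import fu_fs, r2_from_parts, tajimas_d

THETA1_CAP = 1e5  # unconstrained post-expansion theta fits are flat beyond this


@dataclass
class MismatchObserved:
    counts: np.ndarray  # pair counts per difference class 0..max
    n: int              # sample size

    @property
    def n_pairs(self) -> float:
        return self.n * (self.n - 1) / 2.0

    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def mean(self) -> float:
        i = np.arange(len(self.counts))
        return float((i * self.counts).sum() / self.counts.sum())


def mismatch_observed(t: HaplotypeTable, demes=None) -> MismatchObserved:
    """Frequency-weighted histogram of pairwise difference counts."""
    sub = t if demes is None else t.subset(demes)
    c = sub.counts.sum(axis=1).astype(int)
    n = int(c.sum())
    if n < 2:
        raise ValueError("mismatch distribution needs n >= 2")
    d = sub.diff_matrix()
    hist = np.zeros(int(d.max()) + 1)
    for h in range(len(c)):
        hist[0] += c[h] * (c[h] - 1) / 2.0
        for g in range(h + 1, len(c)):
            hist[d[h, g]] += c[h] * c[g]
    return MismatchObserved(hist, n)


def _geometric_pmf(theta: float, kmax: int) -> np.ndarray:
    i = np.arange(kmax + 1)
    if theta <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    return np.exp(i * np.log(theta) - (i + 1) * np.log(theta + 1.0))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, max_class: int, normalize: bool = True
) -> np.ndarray:
    """Sudden-expansion mismatch probabilities F(i) for i = 0..max_class."""
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise ValueError("parameters must be non-negative (theta1 > 0)")
    i = np.arange(max_class + 1)
    a1 = (theta1 + 1.0) / theta1
    recent = _geometric_pmf(theta1, max_class) * gammainc(i + 1, a1 * tau)
    geo0 = _geometric_pmf(theta0, max_class)
    pois = poisson.pmf(i, tau) if tau > 0 else np.eye(1, max_class + 1, 0)[0]
    conv = np.convolve(pois, geo0)[: max_class + 1]
    F = recent + np.exp(-tau / theta1) * conv
    if normalize:
        s = F.sum()
        if s > 0:
            F = F / s
    return F


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float | None = None

    def as_dict(self) -> dict:
        return {
            "tau": self.tau,
            "theta0": self.theta0,
            "theta1": self.theta1,
            "ssd": self.ssd,
            "p_ssd": self.p_ssd,
        }


def _ssd(params: np.ndarray, freqs: np.ndarray) -> float:
    u, v, w = params
    tau = u * u
    theta0 = v * v
    theta1 = min(theta0 + w * w + 1e-9, THETA1_CAP)
    F = expected_mismatch(tau, theta0, theta1, len(freqs) - 1)
    return float(((freqs - F) ** 2).sum())


_TAU_GRID = (0.1, 1.0, 2.0, 5.0, 10.0)
_THETA0_GRID = (0.0, 0.5, 2.0)
_THETA1_GRID = (10.0, 100.0, 1000.0)


def fit_expansion(
    obs: MismatchObserved, starts=None, n_refine: int = 3
) -> ExpansionFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed mismatch.

    The fixed multistart grid is screened by a single SSD evaluation and
    the ``n_refine`` most promising starts are polished by Nelder-Mead
    (the SSD surface is smooth, so a few refinements recover the global
    optimum); theta1 is capped (the surface is flat in theta1 once it is
    large) and the expansion constraint theta0 <= theta1 is built into
    the parameterization.
    """
    freqs = obs.freqs()
    nz = np.nonzero(obs.counts)[0]
    if len(nz) < 2:
        warnings.warn("degenerate single-class histogram; returning tau = 0 fit")
        return ExpansionFit(0.0, 0.0, 1e-9, 0.0)
    if starts is None:
        starts = [
            (t, q0, q1)
            for t in _TAU_GRID
            for q0 in _THETA0_GRID
            for q1 in _THETA1_GRID
        ]
        # a moment-matched start: mismatch mean ~ tau + theta0
        starts.append((max(obs.mean, 0.1), 0.0, 100.0))
    x0s = [
        np.array([np.sqrt(t), np.sqrt(q0), np.sqrt(max(q1 - q0, 1e-6))])
        for t, q0, q1 in starts
    ]
    screened = sorted(x0s, key=lambda x: _ssd(x, freqs))[: max(n_refine, 1)]
    best = None
    for x0 in screened:
        r = minimize(_ssd, x0, args=(freqs,), method="Nelder-Mead",
                     options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
        if best is None or r.fun < best[0]:
            best = (r.fun, r.x)
    u, v, w = best[1]
    theta0 = v * v
    return ExpansionFit(
        tau=float(u * u),
        theta0=float(theta0),
        theta1=float(min(theta0 + w * w + 1e-9, THETA1_CAP)),
        ssd=float(best[0]),
    )


# ---------------------------------------------------------------------------
# coalescent machinery for p-values


def _pairwise_hist(g: sim.Genealogy, muts: np.ndarray) -> np.ndarray:
    """Histogram of pairwise differences implied by mutation-labelled branches."""
    n = g.n
    mutated = np.nonzero(muts)[0]
    if len(mutated) == 0:
        return np.array([n * (n - 1) / 2.0])
    X = np.zeros((len(mutated), n))
    for row, b in enumerate(mutated):
        mask = g.leafmask[b]
        for i in range(n):
            if mask >> i & 1:
                X[row, i] = 1.0
    m = muts[mutated].astype(float)
    r = m @ X
    A = (X * m[:, None]).T @ X
    d = r[:, None] + r[None, :] - 2 * A
    iu = np.triu_indices(n, 1)
    vals = np.rint(d[iu]).astype(int)
    return np.bincount(vals)


def simulate_expansion_mismatch(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> MismatchObserved:
    """One coalescent draw of a mismatch histogram under sudden expansion."""
    g = sim.expansion_genealogy(n, tau, theta0, theta1, rng)
    muts = sim.mutations_poisson(g, 0.5, rng)  # branch lengths are in 2u units
    return MismatchObserved(_pairwise_hist(g, muts), n)


def ssd_pvalue(
    fit: ExpansionFit, n: int, n_boot: int = 1000, seed=None
) -> float:
    """Parametric-bootstrap p-value for the SSD goodness-of-fit statistic.

    Simulates ``n_boot`` coalescent samples of size n under the fitted
    sudden-expansion history, refits each (warm-started at the fitted
    parameters), and reports the fraction with SSD >= the observed SSD.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value")
    rng = np.random.default_rng(seed)
    warm = [
        (fit.tau, fit.theta0, min(fit.theta1, THETA1_CAP)),
        (max(fit.tau, 0.5), 0.0, 100.0),
        (2.0, 0.5, 1000.0),
    ]
    count_ge = 0
    for _ in range(n_boot):
        obs_b = simulate_expansion_mismatch(n, fit.tau, fit.theta0, fit.theta1, rng)
        fb = fit_expansion(obs_b, starts=warm)
        if fb.ssd >= fit.ssd - 1e-15:
            count_ge += 1
    return count_ge / n_boot


_NEUTRAL_STATS = ("tajima_d", "fu_fs", "r2")


def neutral_null_stats(
    n: int, S: int | None, n_sims: int, rng: np.random.Generator,
    theta: float | None = None,
) -> dict:
    """Arrays of D, Fs and R2 over standard neutral simulations.

    Conditioning: exactly ``S`` mutations per genealogy when ``S`` is
    given (fixed-S, infinite sites), or Poisson mutations at rate
    ``theta``/2 per coalescent-unit branch length when ``theta`` is
    given.  Under fixed-theta, replicates where a statistic is undefined
    (S = 0) are recorded as +inf so they never fall in the lower
    (expansion-direction) tail.
    """
    if (S is None) == (theta is None):
        raise ValueError("condition on exactly one of S or theta")
    out = {k: np.empty(n_sims) for k in _NEUTRAL_STATS}
    for r in range(n_sims):
        g = sim.neutral_genealogy(n, rng)
        if S is not None:
            muts = sim.mutations_fixed_s(g, S, rng)
            S_r = S
        else:
            muts = sim.mutations_poisson(g, theta / 2.0, rng)
            S_r = int(muts.sum())
        if S_r < 1:
            for k in _NEUTRAL_STATS:
                out[k][r] = np.inf
            continue
        bs = sim.branch_summaries(g, muts, rng)
        out["tajima_d"][r] = tajimas_d(n, S_r, bs.k_mean)
        out["fu_fs"][r] = fu_fs(n, bs.k_mean, bs.NH)
        out["r2"][r] = r2_from_parts(bs.U, bs.k_mean, S_r)
    return out


def neutrality_type_i_error(
    n: int,
    theta: float,
    n_reps: int = 2000,
    n_null: int = 499,
    alpha: float = 0.05,
    seed=None,
) -> dict:
    """Empirical type-I error of the coalescent neutrality tests.

    Simulates ``n_reps`` datasets under the constant-size neutral
    coalescent at mutation parameter ``theta``, computes D, Fs and R2
    with their fixed-S p-values, and reports the fraction rejected at
    level ``alpha``.  Null distributions are generated once per distinct
    observed S and shared across replicates with that S.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    obs = []
    for _ in range(n_reps):
        g = sim.neutral_genealogy(n, rng)
        muts = sim.mutations_poisson(g, theta / 2.0, rng)
        S = int(muts.sum())
        if S < 1:
            continue
        bs = sim.branch_summaries(g, muts, rng)
        obs.append(
            (S, tajimas_d(n, S, bs.k_mean), fu_fs(n, bs.k_mean, bs.NH),
             r2_from_parts(bs.U, bs.k_mean, S))
        )
    nulls = {}
    for S in sorted({o[0] for o in obs}):
        arr = np.empty((n_null, 3))
        for r in range(n_null):
            g = sim.neutral_genealogy(n, rng)
            muts = sim.mutations_fixed_s(g, S, rng)
            bs = sim.branch_summaries(g, muts, rng)
            arr[r] = (
                tajimas_d(n, S, bs.k_mean),
                fu_fs(n, bs.k_mean, bs.NH),
                r2_from_parts(bs.U, bs.k_mean, S),
            )
        nulls[S] = arr
    rej = np.zeros(3)
    for S, *vals in obs:
        a = nulls[S]
        for j, v in enumerate(vals):
            p = ((a[:, j] <= v + 1e-12).sum() + 1) / (n_null + 1)
            rej[j] += p <= alpha
    rej /= len(obs)
    return dict(zip(_NEUTRAL_STATS, rej)) | {"n_datasets": len(obs)}


def neutrality_pvalue(
    stat_name: str,
    observed: float,
    n: int,
    S: int | None = None,
    n_sims: int = 10_000,
    seed=None,
    theta: float | None = None,
) -> float:
    """One-tailed (lower) coalescent p-value for a neutrality statistic.

    The null is the standard constant-size neutral coalescent,
    conditioned either on exactly S mutations dropped uniformly on the
    realized genealogy (fixed-S, pass ``S``) or on the scaled mutation
    rate (fixed-theta, pass ``theta``; the conditioning DnaSP applies to
    Fu's Fs, where theta is estimated by the observed mean pairwise
    difference).  Negative D/Fs and small R2 indicate expansion, hence
    the lower tail for all three.
    """
    if stat_name not in _NEUTRAL_STATS:
        raise ValueError(f"unknown statistic {stat_name!r}; use {_NEUTRAL_STATS}")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    null = neutral_null_stats(n, S, n_sims, rng, theta=theta)[stat_name]
    return float(((null <= observed + 1e-12).sum() + 1) / (n_sims + 1))
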