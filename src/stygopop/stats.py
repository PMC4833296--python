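"""Population-genetic summary statistics on haplotype tables.

Implements the classic single-locus estimators for mtDNA sequence data:
haplotype diversity h and nucleotide diversity pi with their Nei (1987)
sampling standard deviations, the mean and variance of pairwise
nucleotide differences, Tajima's D, Fu's Fs (via the Ewens sampling
formula with log-space Stirling numbers), the Ramos-Onsins & Rozas R2
statistic, and AMOVA-type pairwise Phi_ST with permutation significance.

Pairwise differences count substitution-variable sites only, keeping S,
k and pi mutually consistent (indel columns are removed upstream when
the haplotype table is built).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given sample."""


# ---------------------------------------------------------------------------
# diversity


def haplotype_diversity(counts) -> tuple:
    """Unbiased haplotype (gene) diversity and its sampling sd.

    h = n(1 - sum p_i^2)/(n - 1); the variance is Nei's (1987, eq. 8.12)
    sampling variance for gene diversity.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p = c / n
    s2 = (p**2).sum()
    s3 = (p**3).sum()
    h = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2
    )
    return float(h), float(np.sqrt(max(var, 0.0)))


def pairwise_difference_moments(t: HaplotypeTable, demes=None) -> tuple:
    """Mean and sample variance of pairwise differences, plus pair count."""
    sub = t if demes is None else t.subset(demes)
    c = sub.counts.sum(axis=1).astype(float)
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError("pairwise differences need n >= 2")
    d = sub.diff_matrix().astype(float)
    npairs = n * (n - 1) / 2.0
    # off-diagonal ordered pairs contribute c_h*c_g, same-hap pairs d=0
    sum_d = (c @ d @ c) / 2.0
    sum_d2 = (c @ (d**2) @ c) / 2.0
    k_mean = sum_d / npairs
    k_var = (sum_d2 - npairs * k_mean**2) / (npairs - 1.0) if npairs > 1 else 0.0
    return float(k_mean), float(max(k_var, 0.0)), npairs


def nucleotide_diversity(t: HaplotypeTable, demes=None) -> tuple:
    """(pi, sd_pi, k_mean, k_var) for a deme subset of a haplotype table.

    pi is the mean proportion of differing sites per pair over the full
    alignment length; its sd follows Nei (1987, eq. 10.7), which includes
    both sampling and stochastic variance.
    """
    sub = t if demes is None else t.subset(demes)
    n = sub.n
    k_mean, k_var, _ = pairwise_difference_moments(sub)
    L = sub.total_length
    pi = k_mean / L
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0))), k_mean, k_var


def segregating_sites(t: HaplotypeTable, demes=None) -> int:
    """Number of sites variable within the (frequency-weighted) subset."""
    sub = t if demes is None else t.subset(demes)
    present = sub.counts.sum(axis=1) > 0
    m = sub.hap_matrix()
    if m.size == 0 or present.sum() == 0:
        return 0
    m = m[present]
    return int(sum(len(set(m[:, j])) > 1 for j in range(m.shape[1])))


@dataclass
class DiversityStats:
    n: int
    S: int
    NH: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    k_mean: float
    k_var: float


def diversity_stats(t: HaplotypeTable, demes=None) -> DiversityStats:
    sub = t if demes is None else t.subset(demes)
    pooled = sub.counts.sum(axis=1)
    h, h_sd = haplotype_diversity(pooled)
    pi, pi_sd, k_mean, k_var = nucleotide_diversity(sub)
    return DiversityStats(
        n=sub.n,
        S=segregating_sites(sub),
        NH=int((pooled > 0).sum()),
        h=h,
        h_sd=h_sd,
        pi=pi,
        pi_sd=pi_sd,
        k_mean=k_mean,
        k_var=k_var,
    )


def diversity_table(t: HaplotypeTable, grouping: dict) -> pd.DataFrame:
    """Per-group (and overall) diversity, one row per group."""
    rows = []
    for g, demes in grouping.items():
        d = diversity_stats(t, demes)
        rows.append({"group": g, **d.__dict__})
    d = diversity_stats(t)
    rows.append({"group": "overall", **d.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neutrality statistics


def tajimas_d(n: int, S: int, k_mean: float) -> float:
    """Tajima's (1989) D from sample size, segregating sites and mean k."""
    if n < 4:
        raise UndefinedStatisticError("Tajima's D needs n >= 4")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0 (NA)")
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((k_mean - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0)))


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple:
    """log unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        hi = m + 2
        prev_shift = row[: hi - 1]  # |s(m, k-1)|
        with np.errstate(divide="ignore"):
            scaled = row[1:hi] + (np.log(m) if m > 0 else -np.inf)
        new[1:hi] = np.logaddexp(scaled, prev_shift)
        row = new
    return tuple(row)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) under the Ewens sampling formula, k = 0..n."""
    if theta <= 0:
        raise UndefinedStatisticError("Ewens distribution needs theta > 0")
    ls = np.array(_log_stirling_row(n))
    k = np.arange(n + 1)
    log_rise = np.log(theta + np.arange(n)).sum()
    with np.errstate(divide="ignore"):
        logp = ls + k * np.log(theta) - log_rise
    logp[0] = -np.inf
    p = np.exp(logp - logp.max())
    return p / p.sum()


def fu_fs(n: int, k_mean: float, NH: int) -> float:
    """Fu's (1997) Fs: ln(S'/(1-S')) with S' = P(K >= NH | theta = k_mean)."""
    if n < 2:
        raise UndefinedStatisticError("Fu's Fs needs n >= 2")
    if k_mean <= 0:
        raise UndefinedStatisticError("Fu's Fs undefined when mean k = 0")
    p = ewens_k_distribution(n, k_mean)
    sp = p[NH:].sum()
    if sp <= 0.0:
        return float("inf")
    if sp >= 1.0:
        return float("-inf")
    return float(np.log(sp / (1.0 - sp)))


def singleton_loads(t: HaplotypeTable, demes=None) -> np.ndarray:
    """Per-sequence singleton-mutation counts U_i.

    A singleton site carries an allele observed in exactly one sequence;
    the count is attributed to that carrier sequence.
    """
    sub = t if demes is None else t.subset(demes)
    pooled = sub.counts.sum(axis=1)
    keep = pooled > 0
    m = sub.hap_matrix()[keep]
    pooled = pooled[keep]
    u_hap = np.zeros(len(pooled))
    for j in range(m.shape[1]):
        col = m[:, j]
        for allele in set(col):
            mask = col == allele
            if pooled[mask].sum() == 1:
                u_hap[mask] += 1
    # expand to sequences: only haplotypes with pooled count 1 can carry one
    U = np.repeat(u_hap, pooled)
    return U


def r2_statistic(t: HaplotypeTable, demes=None) -> float:
    """Ramos-Onsins & Rozas (2002) R2."""
    sub = t if demes is None else t.subset(demes)
    n = sub.n
    if n < 2:
        raise UndefinedStatisticError("R2 needs n >= 2")
    S = segregating_sites(sub)
    if S < 1:
        raise UndefinedStatisticError("R2 undefined for S = 0")
    k_mean, _, _ = pairwise_difference_moments(sub)
    U = singleton_loads(sub)
    return float(np.sqrt(((U - k_mean / 2.0) ** 2).sum() / n) / S)


def r2_from_parts(U: np.ndarray, k_mean: float, S: int) -> float:
    """R2 from precomputed singleton loads (used by the simulation null)."""
    n = len(U)
    return float(np.sqrt(((U - k_mean / 2.0) ** 2).sum() / n) / S)


# ---------------------------------------------------------------------------
# pairwise Phi_ST


@dataclass
class PairwiseFstMatrix:
    group_ids: list
    fst: np.ndarray
    p: np.ndarray
    between_k: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fst, index=self.group_ids, columns=self.group_ids)


def _phi_st_two_groups(d2: np.ndarray, c1: np.ndarray, c2: np.ndarray) -> float:
    """Two-level AMOVA Phi_ST from hap squared distances and group counts."""
    n1, n2 = c1.sum(), c2.sum()
    N = n1 + n2
    w1 = c1 @ d2 @ c1 / 2.0
    w2 = c2 @ d2 @ c2 / 2.0
    ct = c1 + c2
    tot = ct @ d2 @ ct / 2.0
    ss_total = tot / N
    ss_within = w1 / n1 + w2 / n2
    ss_among = ss_total - ss_within
    df_w = N - 2
    if df_w <= 0:
        return np.nan
    ms_w = ss_within / df_w
    ms_a = ss_among / 1.0
    n_c = N - (n1**2 + n2**2) / N
    sigma_a = (ms_a - ms_w) / n_c
    denom = sigma_a + ms_w
    if denom == 0:
        return 0.0  # monomorphic pool: no variance to apportion
    return float(sigma_a / denom)  # may be slightly negative, as in AMOVA


def pairwise_fst(
    t: HaplotypeTable,
    grouping: dict,
    n_perm: int = 10_000,
    seed=None,
    distance: str = "pairwise",
) -> PairwiseFstMatrix:
    """Pairwise Phi_ST between groups with permutation p-values.

    ``grouping`` maps group_id -> list of deme_ids.  The distance between
    haplotypes is the number of differing sites (``"pairwise"``, the
    AMOVA/Arlequin default for sequences) or haplotype identity 0/1
    (``"identity"``, a pure frequency F_ST).
    """
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    groups = list(grouping)
    G = len(groups)
    if G < 2:
        raise ValueError("need at least two groups")
    d = t.diff_matrix().astype(float)
    d2 = d if distance == "pairwise" else (d > 0).astype(float)
    if distance not in ("pairwise", "identity"):
        raise ValueError("distance must be 'pairwise' or 'identity'")
    # pooled per-group haplotype counts
    deme_idx = {dm: j for j, dm in enumerate(t.deme_ids)}
    gcounts = []
    for g in groups:
        idx = [deme_idx[dm] for dm in grouping[g]]
        gcounts.append(t.counts[:, idx].sum(axis=1))
    fst = np.zeros((G, G))
    pmat = np.zeros((G, G))
    between = np.zeros((G, G))
    for a in range(G):
        for b in range(a + 1, G):
            c1, c2 = gcounts[a], gcounts[b]
            n1, n2 = c1.sum(), c2.sum()
            if n1 < 2 or n2 < 2:
                fst[a, b] = fst[b, a] = np.nan
                pmat[a, b] = pmat[b, a] = np.nan
                continue
            obs = _phi_st_two_groups(d2, c1, c2)
            between[a, b] = between[b, a] = float(c1 @ d @ c2 / (n1 * n2))
            # permutation: reassign sequences between the two groups
            seq_h = np.repeat(np.arange(t.n_haplotypes), c1 + c2)
            count_ge = 0
            for _ in range(n_perm):
                rng.shuffle(seq_h)
                p1 = np.bincount(seq_h[:n1], minlength=t.n_haplotypes)
                p2 = np.bincount(seq_h[n1:], minlength=t.n_haplotypes)
                if _phi_st_two_groups(d2, p1, p2) >= obs - 1e-12:
                    count_ge += 1
            fst[a, b] = fst[b, a] = obs
            pmat[a, b] = pmat[b, a] = (count_ge + 1) / (n_perm + 1)
    return PairwiseFstMatrix(groups, fst, pmat, between)
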