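import math

import numpy as np
import pytest
import sympy
from scipy import stats as sps

from stygopop import sim
from stygopop.haplotypes import HaplotypeTable
from stygopop.stats import (
    UndefinedStatisticError,
    diversity_stats,
    ewens_k_distribution,
    fu_fs,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_difference_moments,
    pairwise_fst,
    r2_statistic,
    singleton_loads,
    tajimas_d,
)


class TestHaplotypeDiversity:
    def test_even_split_matches_published_value(self):
        # two haplotypes at 3/3 in a sample of six
        h, sd = haplotype_diversity([3, 3])
        assert h == pytest.approx(0.600, abs=1e-9)
        assert sd == pytest.approx(0.129, abs=5e-4)

    def test_monomorphic_is_zero(self):
        assert haplotype_diversity([6])[0] == 0.0

    def test_all_distinct_is_one(self):
        assert haplotype_diversity([1, 1, 1, 1])[0] == pytest.approx(1.0)

    def test_needs_two_sequences(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity([1])

    def test_invariant_to_relabeling(self, rng):
        counts = rng.integers(1, 9, size=7)
        h1, _ = haplotype_diversity(counts)
        h2, _ = haplotype_diversity(rng.permutation(counts))
        assert h1 == pytest.approx(h2)


class TestNucleotideDiversity:
    def test_two_haplotypes_two_sites(self):
        # mirrors the smallest study group: 3+3 sequences, 2 differing
        # sites over 1,217 bp -> k = 18/15 = 1.2, pi ~ 0.0010 +- 0.0008
        t = HaplotypeTable(["AA", "GG"], [[3], [3]], ["d1"], 1217)
        pi, sd, k_mean, k_var = nucleotide_diversity(t)
        assert k_mean == pytest.approx(1.2)
        assert pi == pytest.approx(0.0010, abs=2e-5)
        assert sd == pytest.approx(0.0008, abs=1e-4)

    def test_identical_sequences_zero(self):
        t = HaplotypeTable(["AA"], [[5]], ["d1"], 100)
        assert nucleotide_diversity(t)[0] == 0.0

    def test_single_pair(self):
        t = HaplotypeTable(["AAAAA", "GGGGG"], [[1], [1]], ["d1"], 100)
        assert nucleotide_diversity(t)[0] == pytest.approx(0.05)

    def test_k_mean_matches_bruteforce_pairs(self, rng):
        for _ in range(10):
            nh = rng.integers(2, 5)
            m = rng.choice(list("ACGT"), size=(nh, 6))
            haps = list(dict.fromkeys("".join(r) for r in m))
            counts = rng.integers(0, 4, size=(len(haps), 2))
            if counts.sum() < 2:
                continue
            t = HaplotypeTable(haps, counts, ["d1", "d2"], 50)
            seqs = []
            for h, row in zip(t.haplotypes, t.counts):
                seqs += [h] * int(row.sum())
            brute = [
                sum(a != b for a, b in zip(seqs[i], seqs[j]))
                for i in range(len(seqs))
                for j in range(i + 1, len(seqs))
            ]
            k_mean, k_var, _ = pairwise_difference_moments(t)
            assert k_mean == pytest.approx(np.mean(brute))
            if len(brute) > 1:
                assert k_var == pytest.approx(np.var(brute, ddof=1))


class TestTajimasD:
    def test_against_exact_rational_oracle(self):
        # independent evaluation of the 1989 coefficients with sympy rationals
        n, S, k = 4, 3, 1.5
        a1 = sum(sympy.Rational(1, i) for i in range(1, n))
        a2 = sum(sympy.Rational(1, i**2) for i in range(1, n))
        b1 = sympy.Rational(n + 1, 3 * (n - 1))
        b2 = sympy.Rational(2 * (n**2 + n + 3), 9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - sympy.Rational(n + 2, a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = float((k - S / a1) / sympy.sqrt(e1 * S + e2 * S * (S - 1)))
        assert tajimas_d(n, S, k) == pytest.approx(expected, rel=1e-12)

    def test_neutral_mean_near_zero(self, rng):
        ds = []
        for _ in range(400):
            g = sim.neutral_genealogy(15, rng)
            m = sim.mutations_poisson(g, 2.5, rng)
            if m.sum() < 1:
                continue
            b = sim.branch_summaries(g, m, rng)
            ds.append(tajimas_d(15, b.S, b.k_mean))
        assert abs(np.mean(ds)) < 0.15

    def test_s_zero_is_undefined_not_zero(self):
        with pytest.raises(UndefinedStatisticError):
            tajimas_d(10, 0, 0.0)


class TestFuFs:
    def test_ewens_distribution_matches_exact_stirling(self):
        # brute-force Ewens probabilities via sympy's exact Stirling numbers
        n, theta = 5, 1.0
        rise = math.prod(theta + i for i in range(n))
        exact = [
            float(sympy.functions.combinatorial.numbers.stirling(n, k, kind=1))
            * theta**k
            / rise
            for k in range(n + 1)
        ]
        got = ewens_k_distribution(n, theta)
        assert np.allclose(got, exact, atol=1e-12)

    def test_fs_from_exact_tail(self):
        n, theta, NH = 5, 1.0, 3
        rise = math.prod(theta + i for i in range(n))
        tail = sum(
            float(sympy.functions.combinatorial.numbers.stirling(n, k, kind=1))
            * theta**k
            / rise
            for k in range(NH, n + 1)
        )
        assert fu_fs(n, theta, NH) == pytest.approx(np.log(tail / (1 - tail)))

    def test_single_haplotype_boundary(self):
        assert fu_fs(10, 2.0, 1) == -np.inf

    def test_large_n_no_overflow(self):
        val = fu_fs(90, 12.17, 49)
        assert np.isfinite(val)


class TestR2:
    def test_two_sequences_one_difference(self):
        t = HaplotypeTable(["A", "T"], [[1], [1]], ["d1"], 100)
        assert r2_statistic(t) == pytest.approx(0.5)

    def test_matches_definition_bruteforce(self, rng):
        for _ in range(10):
            m = rng.choice(list("ACGT"), size=(5, 8), p=[0.7, 0.1, 0.1, 0.1])
            haps = list(dict.fromkeys("".join(r) for r in m))
            counts = np.ones((len(haps), 1), dtype=int)
            t = HaplotypeTable(haps, counts, ["d1"], 50)
            S = sum(
                len({h[j] for h in haps}) > 1 for j in range(8)
            )
            if S == 0:
                continue
            k_mean, _, _ = pairwise_difference_moments(t)
            U = singleton_loads(t)
            expected = np.sqrt(((U - k_mean / 2) ** 2).sum() / len(haps)) / S
            assert r2_statistic(t) == pytest.approx(expected)

    def test_star_genealogy_small_r2(self):
        # every sequence carries one private mutation: minimal R2 regime
        haps = ["".join("T" if j == i else "A" for j in range(6)) for i in range(6)]
        t = HaplotypeTable(haps, np.ones((6, 1), int), ["d1"], 100)
        star = r2_statistic(t)
        # compare with a deeply structured sample of the same n and S
        t2 = HaplotypeTable(["AAAAAA", "TTTTTT"], [[3], [3]], ["d1"], 100)
        assert star < r2_statistic(t2)


class TestPairwiseFst:
    def test_fixed_difference_is_one(self):
        t = HaplotypeTable(["AAA", "TTT"], [[4, 0], [0, 4]], ["d1", "d2"], 50)
        f = pairwise_fst(t, {"a": ["d1"], "b": ["d2"]}, n_perm=99, seed=1)
        assert f.fst[0, 1] == pytest.approx(1.0)
        assert f.p[0, 1] < 0.05
        assert f.between_k[0, 1] == pytest.approx(3.0)

    def test_matrix_structure(self, study_table, study_grouping):
        f = pairwise_fst(study_table, study_grouping, n_perm=60, seed=2)
        assert np.allclose(f.fst, f.fst.T)
        assert np.all(np.diag(f.fst) == 0)
        assert np.nanmax(f.fst) <= 1.0 + 1e-12

    def test_null_split_calibrated(self, rng):
        # one panmictic coalescent pool randomly split into two pseudo-demes:
        # Phi_ST ~ 0 and rejection at the 5% level stays nominal
        ps, fs = [], []
        for r in range(250):
            g = sim.neutral_genealogy(16, rng)
            m = sim.mutations_poisson(g, 3.0, rng)
            if m.sum() < 2:
                continue
            cols = []
            for b in np.nonzero(m)[0]:
                cols += [[(g.leafmask[b] >> i) & 1 for i in range(16)]] * int(m[b])
            X = np.array(cols).T
            seqs = ["".join("AT"[v] for v in row) for row in X]
            uniq = list(dict.fromkeys(seqs))
            counts = np.zeros((len(uniq), 2), int)
            for idx, i in enumerate(rng.permutation(16)):
                counts[uniq.index(seqs[i]), 0 if idx < 8 else 1] += 1
            t = HaplotypeTable(uniq, counts, ["d1", "d2"], 500)
            f = pairwise_fst(t, {"a": ["d1"], "b": ["d2"]}, n_perm=99, seed=100 + r)
            ps.append(f.p[0, 1])
            fs.append(f.fst[0, 1])
        assert abs(np.mean(fs)) < 0.05
        rej = np.mean(np.array(ps) <= 0.05)
        assert 0.01 <= rej <= 0.09

    def test_requires_seed(self, toy_table):
        with pytest.raises(ValueError, match="seed"):
            pairwise_fst(toy_table, {"a": ["d1"], "b": ["d2"]}, n_perm=10)


def test_diversity_stats_consistency(study_table, study_grouping):
    d = diversity_stats(study_table)
    assert d.n == 90
    assert d.NH <= d.n
    assert 0 <= d.h <= 1
    assert d.k_mean == pytest.approx(d.pi * study_table.total_length)
    for g, demes in study_grouping.items():
        dg = diversity_stats(study_table, demes)
        assert dg.n == sum(
            study_table.counts[:, study_table.deme_ids.index(dm)].sum()
            for dm in demes
        )
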