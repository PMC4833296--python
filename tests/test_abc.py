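import numpy as np
import pytest
from scipy import stats as sps

from stygopop import abc as abcmod
from stygopop.abc import (
    DemographicScenario,
    PriorSpec,
    build_reference_table,
    default_priors,
    load_scenarios,
    model_choice,
    simulate_coalescent,
    summarize,
    summary_labels,
    _disperse,
)
from stygopop.haplotypes import HaplotypeTable
from stygopop.stats import pairwise_difference_moments, segregating_sites


class TestScenarios:
    @pytest.mark.parametrize(
        "name, count, n_pops",
        [("major", 3, 3), ("matanzas", 3, 2), ("pinar", 2, 2)],
    )
    def test_builtin_sets(self, name, count, n_pops):
        scen = load_scenarios(name)
        assert len(scen) == count
        assert all(len(s.pops) == n_pops for s in scen)

    def test_stepping_stone_backward_order(self):
        # scenario 3: P merges into H before H merges into M
        sc = [s for s in load_scenarios("major") if s.scenario_id == "3"][0]
        params = {"N_P": 1e3, "N_H": 1e4, "N_M": 5e3, "N_anc": 1e5,
                  "Nf_P": 10, "Bd_P": 20, "Nf_H": 10, "Bd_H": 20,
                  "t0": 1e4, "t1": 5e4, "mu": 5e-8}
        epochs, merges = sc.build(params)
        assert merges == [(1e4, "P", "H"), (5e4, "H", "M")]
        # founder bottleneck precedes each merge
        assert (1e4 - 20, 10) in [(t, N) for t, N in epochs["P"]]

    def test_bad_time_ordering_rejected(self):
        sc = [s for s in load_scenarios("major") if s.scenario_id == "3"][0]
        params = {"N_P": 1e3, "N_H": 1e4, "N_M": 5e3, "N_anc": 1e5,
                  "Nf_P": 10, "Bd_P": 20, "Nf_H": 10, "Bd_H": 20,
                  "t0": 5e4, "t1": 1e4, "mu": 5e-8}  # t0 > t1: P merges late
        with pytest.raises(ValueError, match="coalesce"):
            sc.build(params)

    def test_unknown_set(self):
        with pytest.raises(ValueError):
            load_scenarios("nope")


class TestPriors:
    def test_constraints_always_hold(self, rng):
        scen = load_scenarios("major")
        priors = default_priors(scen)
        for _ in range(2000):
            d = priors.sample(rng)
            assert d["t1"] > d["t0"]
            assert d["N_anc"] > max(d["N_P"], d["N_H"], d["N_M"])
            assert d["N_H"] > d["N_M"] > d["N_P"]

    def test_point_priors_are_deterministic(self, rng):
        spec = PriorSpec({"x": ("uniform", 3.0, 3.0), "y": ("loguniform", 2.0, 2.0)})
        draws = {tuple(spec.sample(rng).values()) for _ in range(10)}
        assert draws == {(3.0, 2.0)}

    def test_uniform_marginal_ks(self, rng):
        spec = PriorSpec({"x": ("uniform", 2.0, 7.0)})
        xs = np.array([spec.sample(rng)["x"] for _ in range(800)])
        assert sps.kstest(xs, sps.uniform(2.0, 5.0).cdf).pvalue > 0.01

    def test_infeasible_constraints_error(self, rng):
        spec = PriorSpec(
            {"a": ("uniform", 0.0, 1.0), "b": ("uniform", 5.0, 6.0)},
            [("a", ">", "b")],
        )
        with pytest.raises(RuntimeError):
            spec.sample(rng, max_tries=500)

    def test_prior_hash_stable(self):
        p1 = default_priors(load_scenarios("pinar"))
        p2 = default_priors(load_scenarios("pinar"))
        assert p1.hash() == p2.hash()


class TestSimulateAndSummarize:
    def test_monomorphic_summary(self):
        t = HaplotypeTable(["AAA"], [[4, 3]], ["g1", "g2"], 100)
        vec = summarize(t, {"g1": ["g1"], "g2": ["g2"]}, include_pairwise=True)
        labels = summary_labels(["g1", "g2"], True)
        d = dict(zip(labels, vec))
        assert d["NH_g1"] == 1 and d["S_g1"] == 0 and d["kmean_g1"] == 0
        assert d["fst_g1_g2"] == 0.0  # undefined -> 0 with flag semantics

    def test_matches_bruteforce_toy(self, toy_table):
        vec = summarize(toy_table, {"a": ["d1"], "b": ["d2"]})
        labels = summary_labels(["a", "b"])
        d = dict(zip(labels, vec))
        sub1 = toy_table.subset(["d1"])
        assert d["NH_a"] == 2
        assert d["S_a"] == segregating_sites(sub1)
        k, kv, _ = pairwise_difference_moments(sub1)
        assert d["kmean_a"] == pytest.approx(k)
        assert d["kvar_a"] == pytest.approx(kv)

    def test_simulated_table_shape(self, rng):
        scen = load_scenarios("pinar")
        priors = default_priors(scen)
        params = priors.sample(rng)
        t = simulate_coalescent(scen[1], params, {"A": 6, "B": 17}, 1217, rng=rng)
        assert t.n == 23
        assert t.deme_ids == ["A", "B"]
        assert t.total_length == 1217

    def test_empty_group_rejected(self, toy_table):
        with pytest.raises(ValueError):
            summarize(toy_table, {"a": ["d1"], "b": ["d2"], "c": []})


class TestReferenceTable:
    def test_one_row_per_scenario(self):
        scen = load_scenarios("pinar")
        priors = default_priors(scen)
        ref = build_reference_table(scen, priors, 1, {"A": 4, "B": 5}, L=300, seed=2)
        assert len(ref.frame) == 2
        assert set(ref.frame.scenario) == {"7", "8"}

    def test_seed_reproducibility(self):
        scen = load_scenarios("pinar")
        priors = default_priors(scen)
        kw = dict(n_sims_per_scenario=5, sample_sizes={"A": 4, "B": 5}, L=300)
        r1 = build_reference_table(scen, priors, seed=3, **kw)
        r2 = build_reference_table(scen, priors, seed=3, **kw)
        assert r1.frame.equals(r2.frame)

    def test_tsv_roundtrip(self, tmp_path):
        scen = load_scenarios("pinar")
        priors = default_priors(scen)
        ref = build_reference_table(scen, priors, 3, {"A": 4, "B": 5}, L=300, seed=4)
        p = tmp_path / "ref.tsv"
        ref.write_tsv(p)
        back = abcmod.ReferenceTable.read_tsv(p)
        assert back.summary_cols == ref.summary_cols
        assert back.meta["prior_hash"] == ref.meta["prior_hash"]
        assert np.allclose(back.summaries(), ref.summaries())

    def test_scenario_1_vs_3_summary_means_differ(self, rng):
        # separability at representative fixed parameters: founding the
        # central population from the east (scenario 3) depresses its
        # within-group diversity relative to the fragmentation history
        scen = {s.scenario_id: s for s in load_scenarios("major")}
        sizes = abcmod.DEFAULT_SAMPLE_SIZES["major"]
        params = {"N_P": 5e3, "N_H": 5e4, "N_M": 2e4, "N_anc": 1e5,
                  "Nf_P": 10, "Bd_P": 30, "Nf_M": 10, "Bd_M": 30,
                  "Nf_H": 10, "Bd_H": 30, "t0": 2e4, "t1": 8e4, "mu": 5e-8}
        km = {sid: [] for sid in ("1", "3")}
        labels = summary_labels(list(sizes))
        for sid in km:
            for _ in range(150):
                t = simulate_coalescent(scen[sid], params, sizes, 1217, rng=rng)
                vec = dict(zip(labels, summarize(t, {g: [g] for g in sizes})))
                km[sid].append(vec["kmean_H"])
        tt = sps.ttest_ind(km["1"], km["3"], equal_var=False)
        assert np.mean(km["1"]) > np.mean(km["3"])
        assert tt.pvalue < 0.01


def _two_separable_scenarios():
    """A deliberately easy two-model problem: small vs large population."""
    lo = DemographicScenario(
        "lo", ["X"], [], {"X": "N_X_lo"}, ancestral_size="N_X_lo"
    )
    hi = DemographicScenario(
        "hi", ["X"], [], {"X": "N_X_hi"}, ancestral_size="N_X_hi"
    )
    priors = PriorSpec(
        {
            "N_X_lo": ("uniform", 200.0, 400.0),
            "N_X_hi": ("uniform", 50_000.0, 80_000.0),
            "mu": ("loguniform", 4e-8, 6e-8),
        }
    )
    return [lo, hi], priors


class TestModelChoice:
    def test_posteriors_sum_to_one_both_estimators(self, rng):
        scen, priors = _two_separable_scenarios()
        ref = build_reference_table(scen, priors, 300, {"X": 15}, L=800, seed=6)
        obs = ref.summaries()[10]
        res = model_choice(ref, obs)
        assert sum(res.logistic.values()) == pytest.approx(1.0, abs=1e-6)
        assert sum(res.rejection.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(0 <= v <= 1 for v in res.logistic.values())

    def test_recovers_separable_scenarios(self, rng):
        scen, priors = _two_separable_scenarios()
        ref = build_reference_table(scen, priors, 400, {"X": 15}, L=800, seed=7)
        hits = 0
        for r in range(30):
            rr = np.random.default_rng([7, r])
            sc = scen[r % 2]
            t = simulate_coalescent(sc, priors.sample(rr), {"X": 15}, 800, rng=rr)
            res = model_choice(ref, summarize(t, {"X": ["X"]}))
            hits += res.best() == sc.scenario_id
            # the two estimators agree on a well-separated problem
            for s in res.logistic:
                assert abs(res.logistic[s] - res.rejection[s]) <= 0.2
        assert hits >= 28

    def test_identical_scenarios_near_half(self):
        sc_a = DemographicScenario("a", ["X"], [], {"X": "N"}, ancestral_size="N")
        sc_b = DemographicScenario("b", ["X"], [], {"X": "N"}, ancestral_size="N")
        priors = PriorSpec({"N": ("uniform", 5_000.0, 20_000.0),
                            "mu": ("loguniform", 4e-8, 6e-8)})
        ref = build_reference_table([sc_a, sc_b], priors, 600, {"X": 12}, L=600, seed=8)
        rng = np.random.default_rng(9)
        t = simulate_coalescent(sc_a, priors.sample(rng), {"X": 12}, 600, rng=rng)
        res = model_choice(ref, summarize(t, {"X": ["X"]}))
        assert res.rejection["a"] == pytest.approx(0.5, abs=0.1)
        assert res.logistic["a"] == pytest.approx(0.5, abs=0.2)

    def test_dimension_mismatch(self):
        scen, priors = _two_separable_scenarios()
        ref = build_reference_table(scen, priors, 20, {"X": 6}, L=300, seed=10)
        with pytest.raises(ValueError):
            model_choice(ref, np.zeros(3))
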