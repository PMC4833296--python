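import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stygopop.haplotypes import HaplotypeTable, SampleMetadata
from stygopop.stats import pairwise_fst
from stygopop.structure import (
    GroupingPartition,
    amova,
    build_contiguity_graph,
    exhaustive_best_bipartition,
    samova,
    _random_contiguous_partition,
)


def _meta_from_coords(coords):
    return SampleMetadata(
        pd.DataFrame(
            [
                {"sample_id": f"s_{d}", "deme_id": d, "lat": la, "lon": lo}
                for d, (la, lo) in coords.items()
            ]
        )
    )


class TestAmova:
    def test_two_single_deme_groups_equal_phist(self, toy_table):
        part = GroupingPartition(["d1", "d2"], {"d1": 0, "d2": 1})
        am = amova(toy_table, part)
        f = pairwise_fst(toy_table, {"a": ["d1"], "b": ["d2"]}, n_perm=20, seed=1)
        assert am.f_ct == pytest.approx(f.fst[0, 1])

    def test_components_match_bruteforce_sums_of_squares(self):
        # 4 demes, 2 groups, n=3 each; oracle computes SS and solves the
        # expected-mean-square equations directly for the balanced design
        rng = np.random.default_rng(7)
        haps = ["AAAA", "AATT", "ATTT", "TTTT", "GTTT"]
        counts = np.zeros((5, 4), int)
        for d in range(4):
            for _ in range(3):
                counts[rng.integers(5), d] += 1
        t = HaplotypeTable(haps, counts, list("wxyz"), 60)
        part = GroupingPartition(list("wxyz"), {"w": 0, "x": 0, "y": 1, "z": 1})
        am = amova(t, part)

        # oracle: expand to sequences, form squared-distance sums explicitly
        seqs, deme = [], []
        for h, row in zip(haps, counts):
            for j, c in enumerate(row):
                seqs += [h] * c
                deme += [j] * c
        seqs = np.array([list(s) for s in seqs])
        deme = np.array(deme)
        d2 = (seqs[:, None, :] != seqs[None, :, :]).sum(axis=2).astype(float)
        N, n_d, D, G = 12, 3, 4, 2
        group_of = np.array([0, 0, 1, 1])

        def ss(idx):
            sub = d2[np.ix_(idx, idx)]
            return sub.sum() / 2.0 / len(idx)

        ss_total = ss(np.arange(N))
        ss_wp = sum(ss(np.nonzero(deme == d)[0]) for d in range(4))
        ss_wg = sum(
            ss(np.nonzero(np.isin(deme, np.nonzero(group_of == g)[0]))[0])
            for g in range(2)
        )
        ms_wp = ss_wp / (N - D)
        ms_ap = (ss_wg - ss_wp) / (D - G)
        ms_ag = (ss_total - ss_wg) / (G - 1)
        # balanced design coefficients: n = n_d, n' = n_d, n'' = n_d * D / G
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / n_d
        sigma_a = (ms_ag - sigma_c - n_d * sigma_b) / (n_d * D / G)
        assert am.variance_components == pytest.approx(
            (sigma_a, sigma_b, sigma_c), rel=1e-10
        )
        tot = sigma_a + sigma_b + sigma_c
        assert am.f_ct == pytest.approx(sigma_a / tot)
        assert am.f_sc == pytest.approx(sigma_b / (sigma_b + sigma_c))

    def test_invariant_to_deme_reordering(self, study_table, study_grouping):
        part = GroupingPartition.from_groups(study_grouping, study_table.deme_ids)
        a1 = amova(study_table, part)
        order = list(reversed(study_table.deme_ids))
        t2 = study_table.subset(order)
        part2 = GroupingPartition.from_groups(
            {g: list(reversed(d)) for g, d in study_grouping.items()}, order
        )
        a2 = amova(t2, part2)
        assert a1.f_ct == pytest.approx(a2.f_ct)
        assert a1.f_sc == pytest.approx(a2.f_sc)

    def test_k1_rejected(self, toy_table):
        with pytest.raises(ValueError):
            amova(toy_table, GroupingPartition(["d1", "d2"], {"d1": 0, "d2": 0}))

    def test_permutation_pvalues(self, study_table, study_grouping):
        part = GroupingPartition.from_groups(study_grouping, study_table.deme_ids)
        am = amova(study_table, part, n_perm=60, seed=3)
        assert 0 < am.p_values["f_ct"] <= 1
        assert 0 < am.p_values["f_sc"] <= 1


class TestContiguityGraph:
    def test_triangle(self):
        g = build_contiguity_graph(
            _meta_from_coords({"a": (0, 0), "b": (0, 1), "c": (1, 0.5)})
        )
        assert g.number_of_edges() == 3

    def test_collinear_chain(self):
        g = build_contiguity_graph(
            _meta_from_coords({"a": (0, 0), "b": (0, 1), "c": (0, 2), "d": (0, 3)})
        )
        assert g.number_of_edges() == 3
        assert all(g.degree[x] <= 2 for x in g)

    def test_study_layout_connected(self, study_like):
        _, meta, _ = study_like
        g = build_contiguity_graph(meta)
        assert nx.is_connected(g)
        assert g.number_of_nodes() == 21


class TestSamova:
    def test_saturated_partition(self, study_table):
        # K = number of demes: the only contiguous partition is singletons
        t = study_table.subset(study_table.deme_ids[:4])
        coords = {d: (0, i) for i, d in enumerate(t.deme_ids)}
        g = build_contiguity_graph(_meta_from_coords(coords))
        best, res, _ = samova(t, g, K=4, n_runs=2, seed=1)
        assert best.K == 4
        assert len(set(best.group_of.values())) == 4

    def test_matches_exhaustive_bipartition(self, study_table, study_like):
        _, meta, _ = study_like
        demes = study_table.deme_ids[:9]
        sub = study_table.subset(demes)
        g = build_contiguity_graph(
            SampleMetadata(meta.table[meta.table.deme_id.isin(demes)])
        )
        _, f_exact = exhaustive_best_bipartition(sub, g)
        _, res, _ = samova(sub, g, K=2, n_runs=8, seed=5)
        assert res.f_ct == pytest.approx(f_exact, abs=1e-9)

    def test_beats_random_contiguous_partitions(self, study_table, study_like):
        _, meta, _ = study_like
        g = build_contiguity_graph(meta)
        best, res, trace = samova(study_table, g, K=3, n_runs=3, seed=9)
        adj = {d: list(g.neighbors(d)) for d in study_table.deme_ids}
        rng = np.random.default_rng(11)
        from stygopop.structure import _fct, _deme_cross_sums

        W = _deme_cross_sums(study_table)
        sizes = study_table.deme_sizes()
        order = {d: i for i, d in enumerate(study_table.deme_ids)}
        for _ in range(100):
            assign = _random_contiguous_partition(study_table.deme_ids, adj, 3, rng)
            groups = [[] for _ in range(3)]
            for d, k in assign.items():
                groups[k].append(order[d])
            assert res.f_ct >= _fct(W, sizes, groups) - 1e-12

    def test_recovers_two_island_structure(self):
        # two strongly diverged islands of 3 demes each
        haps = ["AAAAAA", "AAAAAT", "TTTTTT", "TTTTTA"]
        counts = np.array(
            [[4, 3, 4, 0, 0, 0], [1, 2, 1, 0, 0, 0],
             [0, 0, 0, 4, 4, 3], [0, 0, 0, 1, 1, 2]]
        )
        demes = [f"d{i}" for i in range(6)]
        t = HaplotypeTable(haps, counts, demes, 50)
        coords = {d: (0, i) for i, d in enumerate(demes)}  # chain west-east
        g = build_contiguity_graph(_meta_from_coords(coords))
        hits = 0
        for run in range(20):
            best, res, _ = samova(t, g, K=2, n_runs=1, seed=100 + run)
            left = {d for d in demes if best.group_of[d] == best.group_of["d0"]}
            hits += left == {"d0", "d1", "d2"}
        assert hits >= 19

    def test_errors(self, study_table, study_like):
        _, meta, _ = study_like
        g = build_contiguity_graph(meta)
        with pytest.raises(ValueError):
            samova(study_table, g, K=99, n_runs=1, seed=1)
        with pytest.raises(ValueError, match="seed"):
            samova(study_table, g, K=2, n_runs=1)
        g2 = nx.Graph()
        g2.add_nodes_from(study_table.deme_ids)
        with pytest.raises(ValueError, match="disconnected"):
            samova(study_table, g2, K=2, n_runs=1, seed=1)
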