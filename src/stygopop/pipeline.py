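"""End-to-end analysis pipeline over an alignment + metadata pair.

Runs haplotype collapsing, per-group diversity, pairwise Phi_ST, SAMOVA,
the statistical-parsimony network, per-group demographic tests and
(optionally) ABC scenario choice, writing per-stage TSVs and a single
machine-readable JSON report.  All randomness flows from the seeds in
the configuration, so a run is reproducible from its archived config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import abc as abcmod
from . import demography, network, stats, structure
from .haplotypes import (
    SampleMetadata,
    classify_sites,
    collapse_haplotypes,
    concatenate,
    read_fasta,
)

log = logging.getLogger("stygopop")


@dataclass
class RunConfig:
    fasta: list                 # one or two locus FASTA paths
    metadata: str
    out_dir: str
    seed: int
    n_perm: int = 1000
    n_coal_sims: int = 10_000
    n_boot: int = 1000
    samova_k: tuple = (2, 5)
    samova_runs: int = 100
    do_network: bool = True
    do_demography: bool = True
    do_abc: bool = False
    abc_scenario_set: str = "major"
    abc_n_sims: int = 30_000
    abc_group_map: dict = field(default_factory=dict)  # group_id -> scenario pop


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    rng_seed = int(cfg.seed)
    report: dict = {"config": {k: str(v) for k, v in cfg.__dict__.items()}}

    log.info("stage: haplotypes")
    alns = [read_fasta(p) for p in cfg.fasta]
    aln = alns[0]
    for other in alns[1:]:
        aln = concatenate(aln, other)
    meta = SampleMetadata.read_tsv(cfg.metadata)
    table = collapse_haplotypes(aln, meta)
    table.write_tsv(out / "haplotypes.tsv")
    sc = classify_sites(aln)
    report["sites"] = {
        "L": aln.length,
        "variable": len(sc.variable_sites),
        "indel": sc.n_indel_sites,
        "transitions": sc.n_transitions,
        "transversions": sc.n_transversions,
        "both": sc.n_both,
    }

    grouping: dict = {}
    for d, g in meta.group_of_deme().items():
        grouping.setdefault(g, []).append(d)

    log.info("stage: diversity")
    div = stats.diversity_table(table, grouping)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    report["diversity"] = div.to_dict(orient="records")

    log.info("stage: pairwise Phi_ST")
    fst = stats.pairwise_fst(table, grouping, n_perm=cfg.n_perm, seed=rng_seed + 1)
    fst.to_frame().to_csv(out / "fst.tsv", sep="\t")
    report["fst"] = {
        "groups": fst.group_ids,
        "fst": fst.fst.tolist(),
        "p": fst.p.tolist(),
    }

    log.info("stage: AMOVA + SAMOVA")
    part = structure.GroupingPartition.from_groups(grouping, table.deme_ids)
    am = structure.amova(table, part, n_perm=cfg.n_perm, seed=rng_seed + 2)
    report["amova"] = {
        "f_ct": am.f_ct, "f_sc": am.f_sc, "f_st": am.f_st,
        "p_values": am.p_values,
    }
    graph = structure.build_contiguity_graph(meta)
    sweep = {}
    for K in range(cfg.samova_k[0], cfg.samova_k[1] + 1):
        best, res, _ = structure.samova(
            table, graph, K, n_runs=cfg.samova_runs, seed=rng_seed + 10 + K
        )
        sweep[K] = {"f_ct": res.f_ct, "partition": best.canonical()}
        best.write_tsv(out / f"samova_K{K}.tsv")
    report["samova"] = sweep

    if cfg.do_network:
        log.info("stage: parsimony network")
        limit = network.parsimony_limit(table.total_length)
        net = network.build_network(table, limit)
        net.write_edge_tsv(out / "network_edges.tsv")
        net.write_graphml(out / "network.graphml")
        report["network"] = {
            "limit": limit,
            "n_components": len(net.components),
            "n_inferred": sum(
                1 for _, d in net.graph.nodes(data=True) if d.get("inferred")
            ),
        }

    if cfg.do_demography:
        log.info("stage: demography")
        dem = {}
        for g, demes in grouping.items():
            sub = table.subset(demes)
            entry: dict = {}
            obs = demography.mismatch_observed(sub)
            fit = demography.fit_expansion(obs)
            fit.p_ssd = demography.ssd_pvalue(
                fit, sub.n, n_boot=cfg.n_boot, seed=rng_seed + 100
            )
            entry["expansion"] = fit.as_dict()
            n, S = sub.n, stats.segregating_sites(sub)
            k_mean, _, _ = stats.pairwise_difference_moments(sub)
            if S >= 1 and n >= 4:
                d_obs = stats.tajimas_d(n, S, k_mean)
                fs_obs = stats.fu_fs(n, k_mean, sub.n_haplotypes) if k_mean > 0 else None
                r2_obs = stats.r2_statistic(sub)
                entry["neutrality"] = {}
                for name, val in (
                    ("tajima_d", d_obs), ("fu_fs", fs_obs), ("r2", r2_obs)
                ):
                    if val is None or not np.isfinite(val):
                        continue
                    p = demography.neutrality_pvalue(
                        name, val, n, S, n_sims=cfg.n_coal_sims, seed=rng_seed + 200
                    )
                    entry["neutrality"][name] = {"value": val, "p": p}
            dem[g] = entry
        report["demography"] = dem

    if cfg.do_abc:
        log.info("stage: ABC scenario choice")
        scen = abcmod.load_scenarios(cfg.abc_scenario_set)
        sizes = abcmod.DEFAULT_SAMPLE_SIZES[cfg.abc_scenario_set]
        gmap = cfg.abc_group_map or {g: g for g in sizes}
        merged = table.merge_demes(
            {d: gmap[g] for g, ds in grouping.items() if g in gmap for d in ds}
        )
        observed = abcmod.summarize(merged, {p: [p] for p in sizes})
        priors = abcmod.default_priors(scen)
        ref = abcmod.build_reference_table(
            scen, priors, cfg.abc_n_sims, sizes, L=table.total_length,
            seed=rng_seed + 300,
        )
        res = abcmod.model_choice(ref, observed)
        report["abc"] = {
            "posterior_logistic": res.logistic,
            "posterior_rejection": res.rejection,
            "n_retained": res.n_retained,
            "prior_hash": priors.hash(),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    log.info("report written to %s", out / "report.json")
    return report
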