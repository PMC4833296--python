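"""Study-shaped synthetic datasets with known ground truth.

Emulates the sampling design of the empirical system this package was
built around: 90 individuals of a cave-restricted fish sampled from 21
caves (demes) along a ~300 km west-east karst corridor, grouped into
five regional populations A..E with sample sizes {6, 17, 29, 23, 15},
sequenced for two concatenated mtDNA fragments totalling 1,217 bp with
~81 segregating sites.  Histories are drawn from the fragmentation /
stepping-stone dispersal scenario family, so every downstream stage
(diversity, SAMOVA, network, demography, ABC) can be exercised against
a known generating process.

The generator writes standard FASTA + metadata TSV + a truth JSON that
suffices to re-simulate the dataset bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import sim
from .abc import DemographicScenario, _disperse
from .haplotypes import Alignment, SampleMetadata
import pandas as pd

# deme layout: (deme_id, group, n) — 21 caves in west-to-east order
DEFAULT_DEMES = [
    ("Jud", "A", 6),
    ("Gri", "B", 1), ("Raj", "B", 2), ("Pat", "B", 3), ("Jag", "B", 3),
    ("Fel", "B", 4), ("Paz", "B", 4),
    ("Par", "C", 4), ("Lec", "C", 3), ("Ban", "C", 7), ("Emi", "C", 8),
    ("Sit", "C", 2), ("JPa", "C", 5),
    ("Chi", "D", 6), ("Pch", "D", 13), ("Vos", "D", 4),
    ("Yag", "E", 1), ("PSa", "E", 4), ("Pzo", "E", 3), ("Car", "E", 4),
    ("Rat", "E", 3),
]

# composite five-population stepping-stone history (forward in time:
# E is oldest, colonizes C, C colonizes B and D-side, B colonizes A),
# expressed backward as dispersal merges with founder bottlenecks
FULL_SCENARIO = DemographicScenario(
    "full3",
    ["A", "B", "C", "D", "E"],
    _disperse("A", "B", "ta")
    + _disperse("D", "E", "td")
    + _disperse("B", "C", "t0")
    + _disperse("C", "E", "t1"),
    {p: f"N_{p}" for p in "ABCDE"},
    description="east-to-west stepping-stone with regional founder events",
)

# default generating parameters: haploid sizes, generations, per-site mu
DEFAULT_PARAMS = {
    "N_A": 4_000.0, "N_B": 9_000.0, "N_C": 30_000.0, "N_D": 9_000.0,
    "N_E": 15_000.0, "N_anc": 30_000.0,
    "Nf_A": 10.0, "Bd_A": 20.0, "Nf_B": 30.0, "Bd_B": 20.0,
    "Nf_C": 50.0, "Bd_C": 20.0, "Nf_D": 30.0, "Bd_D": 20.0,
    "ta": 5_000.0, "td": 5_000.0, "t0": 15_000.0, "t1": 50_000.0,
    "mu": 1.3e-7,
}


@dataclass
class StudyTemplate:
    demes: list = field(default_factory=lambda: list(DEFAULT_DEMES))
    L: int = 1217
    scenario: DemographicScenario = field(default_factory=lambda: FULL_SCENARIO)
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    kappa: float = 4.75

    def __post_init__(self):
        if any(n <= 0 for _, _, n in self.demes):
            raise ValueError("deme sample sizes must be positive")

    def group_sizes(self) -> dict:
        out: dict = {}
        for _, g, n in self.demes:
            out[g] = out.get(g, 0) + n
        return out

    def grouping(self) -> dict:
        out: dict = {}
        for d, g, _ in self.demes:
            out.setdefault(g, []).append(d)
        return out


def _coordinates(demes, rng) -> dict:
    """Noisy west-east line mirroring the corridor geography."""
    xs = np.linspace(-84.5, -80.9, len(demes))
    return {
        d: (22.2 + 0.25 * float(rng.normal()), float(x + 0.02 * rng.normal()))
        for (d, _, _), x in zip(demes, xs)
    }


def generate_study_like(template: StudyTemplate | None = None, seed=None) -> tuple:
    """Simulate a full study-shaped dataset.

    Returns ``(Alignment, SampleMetadata, truth)`` where truth records
    the scenario, parameters and seed needed to re-simulate.
    """
    if template is None:
        template = StudyTemplate()
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    sizes = template.group_sizes()
    epochs, merges = template.scenario.build(template.params)
    g = sim.scenario_genealogy(sizes, epochs, merges, rng)
    states, positions = sim.sequence_matrix(
        g, template.params["mu"], template.L, rng, template.kappa
    )

    background = "".join(sim.BASES[b] for b in rng.integers(0, 4, size=template.L))
    # leaves are grouped by population in dict order; hand them to demes
    leaf_by_group: dict = {}
    for i, p in enumerate(g.leaf_pop):
        leaf_by_group.setdefault(p, []).append(i)
    coords = _coordinates(template.demes, rng)
    records, meta_rows = [], []
    counter = 0
    for deme, group, n in template.demes:
        for _ in range(n):
            leaf = leaf_by_group[group].pop()
            seq = list(background)
            for col, pos in enumerate(positions):
                seq[pos] = sim.BASES[states[leaf, col]]
            counter += 1
            sid = f"ind{counter:03d}_{deme}"
            records.append((sid, "".join(seq)))
            lat, lon = coords[deme]
            meta_rows.append(
                {"sample_id": sid, "deme_id": deme, "lat": lat, "lon": lon,
                 "group_id": group}
            )
    aln = Alignment(records)
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = {
        "seed": int(seed),
        "scenario": template.scenario.scenario_id,
        "params": dict(template.params),
        "L": template.L,
        "kappa": template.kappa,
        "demes": [list(d) for d in template.demes],
    }
    return aln, meta, truth


def generate_expansion_sample(
    n: int, tau: float, theta0: float, theta1: float, L: int = 1217, seed=None
) -> Alignment:
    """Coalescent sample under sudden expansion, as an alignment.

    Branch lengths of the expansion genealogy are in mutational units
    (1/(2u) generations), so a per-site rate of 1/(2L) reproduces the
    intended pairwise-difference scale on L sites.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    g = sim.expansion_genealogy(n, tau, theta0, theta1, rng)
    states, positions = sim.sequence_matrix(g, 1.0 / (2.0 * L), L, rng)
    background = "".join(sim.BASES[b] for b in rng.integers(0, 4, size=L))
    records = []
    for i in range(n):
        seq = list(background)
        for col, pos in enumerate(positions):
            seq[pos] = sim.BASES[states[i, col]]
        records.append((f"ind{i + 1:03d}", "".join(seq)))
    return Alignment(records)


def write_dataset(aln, meta, truth, out_dir) -> None:
    from pathlib import Path
    from .haplotypes import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(aln, out / "sequences.fasta")
    meta.write_tsv(out / "metadata.tsv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
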