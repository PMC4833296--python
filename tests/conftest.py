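import numpy as np
import pytest

from stygopop import synthdata
from stygopop.haplotypes import HaplotypeTable, collapse_haplotypes


@pytest.fixture(scope="session")
def study_like():
    """One study-shaped synthetic dataset shared across the suite."""
    aln, meta, truth = synthdata.generate_study_like(seed=20160415)
    return aln, meta, truth


@pytest.fixture(scope="session")
def study_table(study_like):
    aln, meta, _ = study_like
    return collapse_haplotypes(aln, meta)


@pytest.fixture(scope="session")
def study_grouping(study_like):
    _, meta, _ = study_like
    grouping = {}
    for d, g in meta.group_of_deme().items():
        grouping.setdefault(g, []).append(d)
    return grouping


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_table():
    """Two demes, three haplotypes with known distances."""
    return HaplotypeTable(
        ["AAAA", "AATT", "TTTT"], [[3, 0], [1, 2], [0, 3]], ["d1", "d2"], 100
    )
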