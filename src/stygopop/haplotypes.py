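"""Alignment handling: reading, concatenation, site classification and
collapsing aligned mtDNA sequences into a haplotype-by-deme count table.

Coordinates are 0-based internally and 1-based wherever they are written
to reports.  The gap character ``-`` is never treated as a substitution
state: a variable column whose variation involves a gap is an indel site
and is excluded from all downstream nucleotide statistics, mirroring the
"complete deletion" convention of DnaSP/Arlequin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_CHARS = set("ACGTN-")
TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """An aligned set of sequences over {A,C,G,T,-,N}."""

    records: list  # list of (sample_id, sequence)
    locus_labels: list | None = None  # optional per-site locus tag

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dups}")
        lengths = {len(r[1]) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        for sid, seq in self.records:
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"sample {sid}: unsupported characters {sorted(bad)} "
                    "(only A,C,G,T,N,- are accepted)"
                )
        if self.locus_labels is not None and len(self.locus_labels) != self.length:
            raise AlignmentError("locus_labels length does not match alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def sample_ids(self) -> list:
        return [r[0] for r in self.records]

    def matrix(self) -> np.ndarray:
        """(n_samples, length) array of single characters."""
        return np.array([list(seq) for _, seq in self.records])


@dataclass
class SampleMetadata:
    """Per-sample deme assignment, coordinates and optional group label."""

    table: pd.DataFrame  # columns: sample_id, deme_id, lat, lon, group_id

    REQUIRED = ("sample_id", "deme_id", "lat", "lon")

    def __post_init__(self):
        for c in self.REQUIRED:
            if c not in self.table.columns:
                raise ValueError(f"metadata missing column {c!r}")
        if "group_id" not in self.table.columns:
            self.table = self.table.assign(group_id=pd.NA)
        if self.table.sample_id.duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if not np.all(np.isfinite(self.table[["lat", "lon"]].to_numpy(float))):
            raise ValueError("non-finite coordinates in metadata")

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "deme_id": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def deme_of(self) -> dict:
        return dict(zip(self.table.sample_id, self.table.deme_id))

    def group_of_deme(self) -> dict:
        return dict(zip(self.table.deme_id, self.table.group_id))

    def deme_coords(self) -> pd.DataFrame:
        return self.table.groupby("deme_id")[["lat", "lon"]].mean()


@dataclass
class SiteClassification:
    variable_sites: list
    indel_sites: list
    n_transitions: int
    n_transversions: int
    n_both: int

    @property
    def n_indel_sites(self) -> int:
        return len(self.indel_sites)

    @property
    def substitution_sites(self) -> list:
        return [s for s in self.variable_sites if s not in set(self.indel_sites)]

    @property
    def ts_tv_ratio(self) -> float:
        denom = self.n_transversions + self.n_both
        num = self.n_transitions + self.n_both
        return num / denom if denom else float("inf")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes over variable sites, with per-deme counts."""

    haplotypes: list            # strings over the variable sites
    counts: np.ndarray          # (n_haplotypes, n_demes) ints
    deme_ids: list
    total_length: int           # full alignment length L, incl. invariant sites
    site_positions: list = field(default_factory=list)  # 0-based, optional

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotype strings must be pairwise distinct")
        if self.counts.shape != (len(self.haplotypes), len(self.deme_ids)):
            raise ValueError("counts shape does not match haplotypes × demes")
        if (self.counts < 0).any():
            raise ValueError("negative haplotype counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_variable_sites(self) -> int:
        return len(self.haplotypes[0]) if self.haplotypes else 0

    def deme_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def hap_matrix(self) -> np.ndarray:
        """(NH, n_sites) char matrix of the haplotype strings."""
        if not self.haplotypes:
            return np.zeros((0, 0), dtype="<U1")
        return np.array([list(h) for h in self.haplotypes])

    def diff_matrix(self) -> np.ndarray:
        """(NH, NH) pairwise Hamming distances over variable sites."""
        m = self.hap_matrix()
        if m.size == 0:
            return np.zeros((self.n_haplotypes, self.n_haplotypes), dtype=int)
        return (m[:, None, :] != m[None, :, :]).sum(axis=2)

    def subset(self, demes) -> "HaplotypeTable":
        idx = [self.deme_ids.index(d) for d in demes]
        sub = self.counts[:, idx]
        keep = sub.sum(axis=1) > 0
        return HaplotypeTable(
            [h for h, k in zip(self.haplotypes, keep) if k],
            sub[keep],
            list(demes),
            self.total_length,
            self.site_positions,
        )

    def merge_demes(self, group_of: dict) -> "HaplotypeTable":
        """Pool demes into groups according to ``{deme_id: group_id}``."""
        groups = list(dict.fromkeys(group_of[d] for d in self.deme_ids))
        out = np.zeros((self.n_haplotypes, len(groups)), dtype=int)
        for j, d in enumerate(self.deme_ids):
            out[:, groups.index(group_of[d])] += self.counts[:, j]
        return HaplotypeTable(
            list(self.haplotypes), out, groups, self.total_length, self.site_positions
        )

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, columns=self.deme_ids)
        df.insert(0, "haplotype", self.haplotypes)
        with open(path, "w") as fh:
            fh.write(f"# total_length={self.total_length}\n")
            if self.site_positions:
                pos1 = ",".join(str(p + 1) for p in self.site_positions)
                fh.write(f"# site_positions_1based={pos1}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "HaplotypeTable":
        total_length = None
        positions: list = []
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "total_length":
                    total_length = int(val)
                elif key.strip() == "site_positions_1based":
                    positions = [int(x) - 1 for x in val.split(",") if x]
        df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"haplotype": str})
        if total_length is None:
            raise ValueError("haplotype table lacks '# total_length=' header")
        return cls(
            df.haplotype.tolist(),
            df.drop(columns="haplotype").to_numpy(int),
            [str(c) for c in df.columns[1:]],
            total_length,
            positions,
        )


# ---------------------------------------------------------------------------


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA; sequences uppercased, U mapped to T."""
    path = Path(path)
    records = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return Alignment(records)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


def concatenate(a: Alignment, b: Alignment, labels=("locus1", "locus2")) -> Alignment:
    """Concatenate two loci, pairing records strictly by sample_id."""
    if b.length == 0:
        return Alignment(list(a.records), a.locus_labels)
    ida, idb = set(a.sample_ids), set(b.sample_ids)
    if ida != idb:
        missing = sorted(ida.symmetric_difference(idb))
        raise AlignmentError(f"sample ids not shared by both loci: {missing}")
    bmap = dict(b.records)
    records = [(sid, seq + bmap[sid]) for sid, seq in a.records]
    tags_a = a.locus_labels if a.locus_labels else [labels[0]] * a.length
    tags_b = b.locus_labels if b.locus_labels else [labels[1]] * b.length
    return Alignment(records, list(tags_a) + list(tags_b))


def classify_sites(a: Alignment) -> SiteClassification:
    """Classify alignment columns into invariant / TS / TV / both / indel.

    A site is variable when at least two distinct non-N states occur.  A
    variable site at which any sequence carries a gap is an indel site.
    Substitution sites are classified by the set of unordered state pairs
    observed in the column.
    """
    if not a.records:
        raise AlignmentError("empty alignment")
    m = a.matrix()
    variable, indels = [], []
    n_ts = n_tv = n_both = 0
    for j in range(a.length):
        col = m[:, j]
        states = set(col) - {"N"}
        if not states:
            warnings.warn(f"column {j + 1} is all-N; excluded", stacklevel=2)
            continue
        if len(states) < 2:
            continue
        variable.append(j)
        if "-" in states:
            indels.append(j)
            states -= {"-"}
            if len(states) < 2:
                continue  # gap-only variation: indel site, no substitution
        pairs = {
            frozenset((x, y))
            for i, x in enumerate(sorted(states))
            for y in sorted(states)[i + 1 :]
        }
        has_ts = any(p in TRANSITIONS for p in pairs)
        has_tv = any(p not in TRANSITIONS for p in pairs)
        if has_ts and has_tv:
            n_both += 1
        elif has_ts:
            n_ts += 1
        else:
            n_tv += 1
    return SiteClassification(variable, indels, n_ts, n_tv, n_both)


def collapse_haplotypes(
    a: Alignment,
    m: SampleMetadata,
    on_ambiguous: str = "exclude",
    include_indels: bool = False,
) -> HaplotypeTable:
    """Collapse aligned sequences to haplotypes over variable sites.

    Sites are the substitution-variable columns (indel columns included
    only when ``include_indels``).  Samples carrying N at a retained site
    are excluded by default, or matched to an existing haplotype when
    ``on_ambiguous="match"`` and the match is unambiguous.
    """
    if on_ambiguous not in ("exclude", "match"):
        raise ValueError("on_ambiguous must be 'exclude' or 'match'")
    deme_of = m.deme_of()
    missing = [sid for sid in a.sample_ids if sid not in deme_of]
    if missing:
        raise ValueError(f"metadata missing samples: {missing}")

    sc = classify_sites(a)
    sites = sorted(sc.variable_sites) if include_indels else sc.substitution_sites
    mat = a.matrix()[:, sites] if sites else np.zeros((len(a.records), 0), dtype="<U1")

    deme_ids = list(dict.fromkeys(deme_of[sid] for sid in a.sample_ids))
    clean_rows = [i for i in range(len(a.records)) if "N" not in set(mat[i])]
    hap_index: dict = {}
    haplotypes: list = []
    rows_count: list = []
    for i in clean_rows:
        key = "".join(mat[i])
        if key not in hap_index:
            hap_index[key] = len(haplotypes)
            haplotypes.append(key)
            rows_count.append(np.zeros(len(deme_ids), dtype=int))
        rows_count[hap_index[key]][deme_ids.index(deme_of[a.sample_ids[i]])] += 1

    for i in set(range(len(a.records))) - set(clean_rows):
        row = mat[i]
        ok = row != "N"
        matches = [
            h for h in haplotypes if all(row[ok] == np.array(list(h))[ok])
        ]
        if on_ambiguous == "match" and len(matches) == 1:
            rows_count[hap_index[matches[0]]][
                deme_ids.index(deme_of[a.sample_ids[i]])
            ] += 1
        else:
            warnings.warn(
                f"sample {a.sample_ids[i]} has N at a variable site; excluded",
                stacklevel=2,
            )
    return HaplotypeTable(haplotypes, np.array(rows_count), deme_ids, a.length, sites)
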