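"""Aligned-sequence input, site masking and haplotype collapsing.

Sequences are assumed pre-aligned mtDNA (e.g. COI amplicons); the module
validates the alignment, associates samples with populations, restricts
analysis to a well-defined site set and collapses identical restricted
sequences into haplotypes with per-population counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, DegenerateDataError, InputError, MetadataError

VALID_BASES = frozenset("ACGTN-")
#: characters treated as missing under complete deletion
MISSING = frozenset("N-")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length DNA sequences over {A,C,G,T,N,-}."""

    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if not self.sequences:
            raise InputError("alignment contains no sequences")
        L = len(self.sequences[0])
        if L == 0:
            raise AlignmentError("zero-length alignment")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"ragged alignment: {sid!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise InputError(
                    f"illegal character(s) {sorted(bad)} in sequence {sid!r}; "
                    "only A,C,G,T,N,- are accepted"
                )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample ids in alignment")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise MetadataError(f"samples not in alignment: {missing}")
        return Alignment(
            tuple(sample_ids),
            tuple(self.sequences[index[s]] for s in sample_ids),
        )


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> (population, lon, lat, grouping labels)."""

    population: Mapping[str, str]
    lon: Mapping[str, float]
    lat: Mapping[str, float]
    groups: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    #: groups maps grouping-scheme name -> {population_id -> group id}

    def __post_init__(self):
        for sid in self.population:
            lo, la = self.lon.get(sid), self.lat.get(sid)
            if lo is None or la is None:
                raise MetadataError(f"missing coordinates for sample {sid!r}")
            if not (-180.0 <= lo <= 180.0 and -90.0 <= la <= 90.0):
                raise MetadataError(f"coordinates out of range for sample {sid!r}")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, population_id: str) -> list[str]:
        return [s for s, p in self.population.items() if p == population_id]

    def population_coords(self) -> dict[str, tuple[float, float]]:
        """Mean (lon, lat) of samples in each population."""
        out: dict[str, tuple[float, float]] = {}
        for pop in self.populations():
            sids = self.samples_of(pop)
            out[pop] = (
                float(np.mean([self.lon[s] for s in sids])),
                float(np.mean([self.lat[s] for s in sids])),
            )
        return out

    def validate_against(self, aln: Alignment) -> None:
        missing = [s for s in aln.sample_ids if s not in self.population]
        if missing:
            raise MetadataError(f"samples missing from population map: {missing}")


@dataclass(frozen=True)
class SiteMask:
    """Included alignment columns under a missing-data policy."""

    included_sites: tuple[int, ...]
    policy: str  # "complete_deletion" | "pairwise_deletion"

    def __post_init__(self):
        if self.policy not in ("complete_deletion", "pairwise_deletion"):
            raise InputError(f"unknown site-mask policy {self.policy!r}")
        if list(self.included_sites) != sorted(set(self.included_sites)):
            raise InputError("included_sites must be sorted and unique")


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique restricted sequences with per-population counts.

    Haplotype ids are ``H1, H2, ...`` in order of decreasing global count
    (ties by first occurrence in the input), matching the convention of
    naming dominant haplotypes H1-H3.
    """

    haplotype_ids: tuple[str, ...]
    site_patterns: tuple[str, ...]
    population_ids: tuple[str, ...]
    counts: np.ndarray  # (n_haplotypes, n_populations) int
    sample_haplotype: Mapping[str, str]  # sample_id -> haplotype_id

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def total_n(self) -> int:
        return int(self.counts.sum())

    def global_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def n_singletons(self) -> int:
        return int((self.global_counts() == 1).sum())

    def population_counts(self, population_id: str | None = None) -> np.ndarray:
        """Haplotype counts for one population, or pooled if None."""
        if population_id is None:
            return self.global_counts()
        try:
            j = self.population_ids.index(population_id)
        except ValueError:
            raise MetadataError(f"unknown population {population_id!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=list(self.haplotype_ids), columns=list(self.population_ids)
        )
        df.insert(0, "total", self.global_counts())
        return df


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read and validate an aligned FASTA file."""
    if format != "fasta":
        raise InputError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no sequences parsed from {path}")
    return Alignment(
        tuple(r.id for r in records),
        tuple(str(r.seq).upper() for r in records),
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def read_population_map(path: str | Path, sep: str = "\t") -> PopulationMap:
    """Read a delimited metadata table.

    Required columns: ``sample_id``, ``population_id``, ``lon``, ``lat``.
    Any additional column is interpreted as a grouping scheme assigning each
    sample's population to a group.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "population_id", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata table missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    groups: dict[str, dict[str, str]] = {}
    for col in extra:
        scheme: dict[str, str] = {}
        for pop, grp in zip(df["population_id"], df[col]):
            pop, grp = str(pop), str(grp)
            if pop in scheme and scheme[pop] != grp:
                raise MetadataError(
                    f"grouping column {col!r} assigns population {pop!r} to "
                    "more than one group"
                )
            scheme[pop] = grp
        groups[col] = scheme
    return PopulationMap(
        population=dict(zip(df["sample_id"].astype(str), df["population_id"].astype(str))),
        lon=dict(zip(df["sample_id"].astype(str), df["lon"].astype(float))),
        lat=dict(zip(df["sample_id"].astype(str), df["lat"].astype(float))),
        groups=groups,
    )


def build_site_mask(
    aln: Alignment, policy: str = "complete_deletion"
) -> SiteMask:
    """Define the analyzable column set.

    ``complete_deletion`` excludes every column containing a gap or N (the
    DnaSP-style default); ``pairwise_deletion`` keeps all columns and defers
    missing-data handling to per-pair comparisons downstream.
    """
    if policy == "pairwise_deletion":
        return SiteMask(tuple(range(aln.length)), policy)
    if policy != "complete_deletion":
        raise InputError(f"unknown site-mask policy {policy!r}")
    M = aln.matrix()
    ok = ~np.isin(M, list(MISSING)).any(axis=0)
    included = tuple(int(i) for i in np.nonzero(ok)[0])
    if not included:
        raise DegenerateDataError("complete deletion removed every column")
    return SiteMask(included, policy)


def restricted_sequences(aln: Alignment, mask: SiteMask) -> list[str]:
    """Sequences restricted to the mask's included columns."""
    cols = list(mask.included_sites)
    return ["".join(seq[i] for i in cols) for seq in aln.sequences]


def collapse_haplotypes(
    aln: Alignment, mask: SiteMask, popmap: PopulationMap
) -> HaplotypeTable:
    """Collapse identical restricted sequences into haplotypes.

    Equivalence is exact string identity on the included sites (under
    pairwise deletion, sequences containing missing characters thus form
    their own classes). Ids are assigned by decreasing global count, ties
    broken by first occurrence in the input.
    """
    popmap.validate_against(aln)
    restricted = restricted_sequences(aln, mask)
    first_seen: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for i, (sid, pat) in enumerate(zip(aln.sample_ids, restricted)):
        if pat not in first_seen:
            first_seen[pat] = i
            members[pat] = []
        members[pat].append(sid)
    patterns = sorted(
        members, key=lambda p: (-len(members[p]), first_seen[p])
    )
    pops = popmap.populations()
    pop_index = {p: j for j, p in enumerate(pops)}
    counts = np.zeros((len(patterns), len(pops)), dtype=int)
    sample_hap: dict[str, str] = {}
    hap_ids = tuple(f"H{i + 1}" for i in range(len(patterns)))
    for i, pat in enumerate(patterns):
        for sid in members[pat]:
            counts[i, pop_index[popmap.population[sid]]] += 1
            sample_hap[sid] = hap_ids[i]
    return HaplotypeTable(
        haplotype_ids=hap_ids,
        site_patterns=tuple(patterns),
        population_ids=tuple(pops),
        counts=counts,
        sample_haplotype=sample_hap,
    )


def count_site_classes(aln: Alignment, mask: SiteMask) -> tuple[int, int, int]:
    """Classify included columns: (S, parsimony-informative, singleton sites).

    A column is polymorphic (counted in S) if it shows >= 2 distinct
    non-missing bases; parsimony-informative if >= 2 bases each occur in
    >= 2 sequences; a singleton site is a polymorphic, non-informative
    column. Missing characters are ignored within each column.
    """
    if aln.n < 2:
        raise DegenerateDataError("site classification needs >= 2 sequences")
    M = aln.matrix()[:, list(mask.included_sites)]
    S = pi_count = singleton = 0
    for j in range(M.shape[1]):
        col = M[:, j]
        col = col[~np.isin(col, list(MISSING))]
        if col.size < 2:
            continue
        _, freqs = np.unique(col, return_counts=True)
        if len(freqs) < 2:
            continue
        S += 1
        if (freqs >= 2).sum() >= 2:
            pi_count += 1
        else:
            singleton += 1
    return S, pi_count, singleton


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="haplotype_id")


def write_haplotype_fasta(table: HaplotypeTable, path: str | Path) -> None:
    """Representative (restricted) sequence of each haplotype as FASTA."""
    with open(path, "w") as fh:
        for hid, pat in zip(table.haplotype_ids, table.site_patterns):
            fh.write(f">{hid}\n{pat}\n")
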