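"""Alignment and population-map I/O, haplotype collapsing and site classification.

The analyses in this package start from a multiple sequence alignment of
mitochondrial control-region sequences (FASTA) and a two-column TSV mapping
each sample to the locality it was collected in.  This module validates those
inputs, removes user-specified alignment columns of ambiguous homology,
collapses identical sequences into haplotypes, and summarises the variable
sites of the alignment.

Coordinates are 0-based, half-open throughout; 1-based numbering appears only
in written reports.  Two sequences are the same haplotype iff they are
identical strings after uppercasing: an ``N`` mismatching a base makes them
distinct (conservative, since no ambiguity-merging rule is assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "PopulationMap",
    "HaplotypeTable",
    "SiteClassification",
    "AlignmentError",
    "read_alignment",
    "read_popmap",
    "mask_sites",
    "collapse_haplotypes",
    "expand_haplotypes",
    "shared_private_summary",
    "classify_sites",
]

_VALID = set("ACGTN-")
# IUPAC ambiguity codes other than N
_AMBIG = set("RYSWKMBDHV")

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class AlignmentError(ValueError):
    """Raised for malformed alignments or sample/population mismatches."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences over the alphabet {A,C,G,T,-,N}.

    Parameters
    ----------
    ids
        Unique sample identifiers, one per sequence.
    seqs
        Equal-length uppercase sequences.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences of unequal length: {sorted(lengths)}")
        if self.length == 0:
            raise AlignmentError("zero-length alignment")
        bad = set("".join(self.seqs)) - _VALID
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """(n, L) array of single characters (dtype '<U1')."""
        return np.array([list(s) for s in self.seqs])

    def subset(self, ids: list[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sequence ids: {missing}")
        return Alignment(tuple(ids), tuple(self.seqs[index[s]] for s in ids))


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of each sample to a population, with a stable population order."""

    assignments: dict[str, str]
    populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.assignments:
            raise AlignmentError("empty population map")
        pops = self.populations or tuple(dict.fromkeys(self.assignments.values()))
        object.__setattr__(self, "populations", pops)
        extra = set(self.assignments.values()) - set(self.populations)
        if extra:
            raise AlignmentError(f"samples assigned to unlisted populations: {sorted(extra)}")

    def of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise AlignmentError(f"sample {sample_id!r} missing from population map") from None

    def sizes(self) -> dict[str, int]:
        out = {p: 0 for p in self.populations}
        for p in self.assignments.values():
            out[p] += 1
        return out

    def labels_for(self, ids: tuple[str, ...] | list[str]) -> list[str]:
        return [self.of(s) for s in ids]


@dataclass
class HaplotypeTable:
    """Distinct haplotypes and their per-population counts.

    ``counts`` is indexed by 1-based haplotype id (order of first appearance)
    with one column per population.
    """

    sequences: tuple[str, ...]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.counts):
            raise AlignmentError("sequence list and count table differ in length")
        if len(set(self.sequences)) != len(self.sequences):
            raise AlignmentError("haplotype sequences must be pairwise distinct")
        if (self.counts.values < 0).any():
            raise AlignmentError("negative haplotype counts")
        if (self.counts.sum(axis=1) < 1).any():
            raise AlignmentError("every haplotype needs total count >= 1")

    @property
    def k(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy()

    def write_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path)


@dataclass
class SiteClassification:
    """Counts of variable-site categories and the average base composition."""

    S: int
    n_transitions: int
    n_transversions: int
    n_indels: int
    variable_sites: list[int]
    base_composition: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.base_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise AlignmentError(f"base composition sums to {total}, not 1")


def read_popmap(popmap_path: str | Path) -> PopulationMap:
    """Read a two-column (sample_id, population) TSV without header."""
    df = pd.read_csv(popmap_path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise AlignmentError(f"empty population map file: {popmap_path}")
    if df.shape[1] < 2:
        raise AlignmentError("population map needs two tab-separated columns")
    assignments = dict(zip(df[0], df[1]))
    if len(assignments) != len(df):
        raise AlignmentError("duplicate sample ids in population map")
    return PopulationMap(assignments)


def read_alignment(
    fasta_path: str | Path,
    popmap_path: str | Path,
    *,
    ambiguous: str = "reject",
) -> tuple[Alignment, PopulationMap]:
    """Read an aligned FASTA and its sample-to-population map.

    Parameters
    ----------
    ambiguous
        ``"reject"`` raises on IUPAC ambiguity codes other than N;
        ``"to_n"`` silently converts them to N.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    ids, seqs = [], []
    for rec in records:
        seq = str(rec.seq).upper()
        hit = set(seq) & _AMBIG
        if hit:
            if ambiguous == "to_n":
                seq = "".join("N" if c in _AMBIG else c for c in seq)
            else:
                raise AlignmentError(
                    f"record {rec.id}: ambiguity codes {sorted(hit)} (set ambiguous='to_n' to convert)"
                )
        ids.append(rec.id)
        seqs.append(seq)
    aln = Alignment(tuple(ids), tuple(seqs))
    popmap = read_popmap(popmap_path)
    unmapped = [s for s in aln.ids if s not in popmap.assignments]
    if unmapped:
        raise AlignmentError(f"samples missing from population map: {unmapped}")
    return aln, popmap


def mask_sites(aln: Alignment, mask_ranges: list[tuple[int, int]]) -> Alignment:
    """Delete the alignment columns in ``mask_ranges`` (0-based, half-open)."""
    if not mask_ranges:
        return aln
    keep = np.ones(aln.length, dtype=bool)
    for start, end in mask_ranges:
        if not (0 <= start <= end <= aln.length):
            raise AlignmentError(f"mask range ({start}, {end}) outside [0, {aln.length})")
        keep[start:end] = False
    if not keep.any():
        raise AlignmentError("masking removed every column")
    seqs = tuple("".join(np.array(list(s))[keep]) for s in aln.seqs)
    return Alignment(aln.ids, seqs)


def collapse_haplotypes(aln: Alignment, popmap: PopulationMap) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes numbered by first appearance."""
    order: dict[str, int] = {}
    for s in aln.seqs:
        if s not in order:
            order[s] = len(order)
    pops = list(popmap.populations)
    counts = np.zeros((len(order), len(pops)), dtype=int)
    pop_index = {p: j for j, p in enumerate(pops)}
    for sid, seq in zip(aln.ids, aln.seqs):
        counts[order[seq], pop_index[popmap.of(sid)]] += 1
    df = pd.DataFrame(counts, columns=pops, index=pd.RangeIndex(1, len(order) + 1, name="haplotype"))
    return HaplotypeTable(tuple(order), df)


def expand_haplotypes(tbl: HaplotypeTable) -> tuple[Alignment, PopulationMap]:
    """Inverse of :func:`collapse_haplotypes`: one record per individual."""
    ids, seqs, assignments = [], [], {}
    for hap_id, seq in zip(tbl.counts.index, tbl.sequences):
        for pop in tbl.counts.columns:
            for rep in range(int(tbl.counts.loc[hap_id, pop])):
                sid = f"{pop}_h{hap_id:03d}_{rep + 1}"
                ids.append(sid)
                seqs.append(seq)
                assignments[sid] = pop
    popmap = PopulationMap(assignments, tuple(tbl.counts.columns))
    return Alignment(tuple(ids), tuple(seqs)), popmap


def shared_private_summary(tbl: HaplotypeTable) -> tuple[int, int, float]:
    """Number of haplotypes seen in >=2 populations, in exactly 1, and the
    percentage of population-specific ('private') haplotypes (1 decimal)."""
    occupancy = (tbl.counts.values > 0).sum(axis=1)
    if tbl.counts.shape[1] < 2:
        warnings.warn("single population: no haplotype can be shared")
        return 0, tbl.k, 100.0
    n_shared = int((occupancy >= 2).sum())
    n_private = tbl.k - n_shared
    return n_shared, n_private, round(100.0 * n_private / tbl.k, 1)


def classify_sites(aln: Alignment) -> SiteClassification:
    """Classify variable alignment columns.

    A column is an indel site if it contains a gap among its non-N characters.
    Every unordered pair of distinct bases observed in a column is counted once
    as a transition (A<->G, C<->T) or a transversion, so a multi-state column
    can contribute to both tallies.  ``S`` counts all columns with >=2 distinct
    non-N states (gaps count as a state).  Base composition is averaged over
    all non-gap, non-N characters.
    """
    arr = aln.to_array()
    S = 0
    n_ts = n_tv = n_indel = 0
    variable: list[int] = []
    base_counts = {b: 0 for b in "ACGT"}
    for j in range(aln.length):
        col = arr[:, j]
        states = set(col) - {"N"}
        for b in "ACGT":
            base_counts[b] += int((col == b).sum())
        if not states:
            warnings.warn(f"column {j} is all-N; excluded from S")
            continue
        if len(states) >= 2:
            S += 1
            variable.append(j)
            if "-" in states:
                n_indel += 1
            bases = states - {"-"}
            for pair in {frozenset((a, b)) for a in bases for b in bases if a != b}:
                if pair in TRANSITIONS:
                    n_ts += 1
                else:
                    n_tv += 1
    total = sum(base_counts.values())
    if total == 0:
        raise AlignmentError("alignment contains no unambiguous bases")
    comp = {b: c / total for b, c in base_counts.items()}
    return SiteClassification(S, n_ts, n_tv, n_indel, variable, comp)
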