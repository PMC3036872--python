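import numpy as np
import pytest

from mtpopgen.alignio import Alignment, PopulationMap
from mtpopgen.datasets import load_fchinensis_counts


@pytest.fixture(scope="session")
def fchinensis_counts():
    return load_fchinensis_counts()


@pytest.fixture()
def toy_alignment():
    """Five sequences over 12 sites with known variable columns.

    Hand-enumerated classification: column 2 and 5 are transitions (A/G,
    C/T), column 8 is a transversion (A/C), column 10 is an indel column.
    """
    seqs = (
        "AAATACGTAC-T",
        "AAGTACGTAC-T",
        "AAGTATGTACAT",
        "AAATACGTCCAT",
        "AAATACGTCCAT",
    )
    ids = tuple(f"s{i}" for i in range(5))
    return Alignment(ids, seqs)


@pytest.fixture()
def two_pop_map():
    return PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "B"}, ("A", "B"))


def write_fasta_popmap(tmp_path, aln: Alignment, popmap: PopulationMap):
    fasta = tmp_path / "aln.fasta"
    pm = tmp_path / "popmap.tsv"
    fasta.write_text("".join(f">{s}\n{q}\n" for s, q in zip(aln.ids, aln.seqs)))
    pm.write_text("".join(f"{s}\t{popmap.of(s)}\n" for s in aln.ids))
    return fasta, pm
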