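"""Bundled reference data.

The package ships the published haplotype-frequency table of the Chinese
shrimp (*Fenneropenaeus chinensis*) control-region survey: 68 haplotypes
scored in 93 individuals from five localities (KW, KS, RS, HZ, LD).  The
full sequences are deposited in GenBank (GQ283010-GQ283077) and are not
redistributed here; the count table alone supports the haplotype-composition
statistics (haplotype diversity, sharing between localities).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fchinensis_counts", "load_fchinensis_samples"]


def load_fchinensis_counts() -> pd.DataFrame:
    """Haplotype (rows, 1..68) by locality (columns) count table."""
    with resources.files("mtpopgen.data").joinpath(
        "fchinensis_haplotype_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh, index_col=0)


def load_fchinensis_samples() -> pd.DataFrame:
    """Sampling localities and sample sizes."""
    with resources.files("mtpopgen.data").joinpath("fchinensis_samples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
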