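"""Readers for the cohort TSV formats.

On-disk coordinates are 1-based inclusive; in memory the package uses
0-based half-open intervals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "subtype": str})


def read_segments(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    seg["start"] = seg["start"] - 1  # back to 0-based half-open
    return seg


def read_variants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})


def read_depths(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_arms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
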