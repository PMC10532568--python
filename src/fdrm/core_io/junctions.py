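"""Junction and region (coverage) evidence TSV dialects.

Junction rows: contig, donor0, acceptor0, sample, reads, clean_overhang_bases.
``donor0`` is the first intronic base, ``acceptor0`` the first base after the
intron (0-based half-open intron = [donor0, acceptor0)). A junction counts as
clean when no mismatch/insertion/deletion occurs within 6 bases of the
alignment overhang, i.e. ``clean_overhang_bases >= 6``.

Region rows: contig, start0, end0, sample, mean_cov — mean read coverage over
an interval; used for intron-retention and novel-exon evidence.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from fdrm.errors import FormatError

CLEAN_OVERHANG_BASES = 6

JUNCTION_COLUMNS = ["contig", "donor0", "acceptor0", "sample", "reads", "clean_overhang_bases"]
REGION_COLUMNS = ["contig", "start0", "end0", "sample", "mean_cov"]


@dataclass(frozen=True)
class JunctionEvidence:
    contig: str
    donor0: int
    acceptor0: int
    sample: str
    reads: int
    clean_overhang_bases: int = CLEAN_OVERHANG_BASES

    def __post_init__(self) -> None:
        if self.donor0 >= self.acceptor0:
            raise FormatError(f"junction donor0 {self.donor0} >= acceptor0 {self.acceptor0}")
        if self.reads < 0:
            raise FormatError("negative junction read count")

    @property
    def clean_overhang(self) -> bool:
        return self.clean_overhang_bases >= CLEAN_OVERHANG_BASES


def read_junction_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "sample": str})
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"junction TSV {path} missing columns {missing}")
    if (df["donor0"] >= df["acceptor0"]).any():
        raise FormatError(f"junction TSV {path}: donor0 >= acceptor0")
    return df[JUNCTION_COLUMNS].copy()


def write_junction_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_region_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "sample": str})
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"region TSV {path} missing columns {missing}")
    return df[REGION_COLUMNS].copy()


def write_region_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[REGION_COLUMNS].to_csv(path, sep="\t", index=False)
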