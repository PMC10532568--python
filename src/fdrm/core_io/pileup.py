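"""Per-position base tallies from quality-filtered reads.

Two input routes are supported: indexed SAM/BAM via pysam, and a plain
TSV dialect (contig, pos0, ref, sample, A, C, G, T, N) that makes the
pipeline testable without alignment files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from fdrm.errors import FormatError

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

PILEUP_COLUMNS = ["contig", "pos0", "ref", "sample", "A", "C", "G", "T", "N"]


@dataclass
class PileupColumn:
    contig: str
    pos0: int
    ref: str
    sample: str
    counts: dict[str, int] = field(default_factory=dict)
    source: str = "RNA"

    @property
    def depth(self) -> int:
        """Sum of A/C/G/T tallies (N excluded)."""
        return sum(self.counts.get(b, 0) for b in BASES)

    def alt_counts(self) -> dict[str, int]:
        return {b: c for b, c in self.counts.items() if b != self.ref and b in BASES and c > 0}


def read_pileup_tsv(path: str | Path, source: str = "RNA") -> pd.DataFrame:
    """Load the pileup TSV dialect into a DataFrame (one row per column/sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "sample": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pileup TSV {path} missing columns {missing}")
    df = df[PILEUP_COLUMNS].copy()
    df["source"] = source
    return df


def write_pileup_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def pileup_rows_to_columns(df: pd.DataFrame) -> Iterator[PileupColumn]:
    for row in df.itertuples(index=False):
        yield PileupColumn(
            contig=row.contig,
            pos0=int(row.pos0),
            ref=row.ref,
            sample=row.sample,
            counts={"A": int(row.A), "C": int(row.C), "G": int(row.G),
                    "T": int(row.T), "N": int(row.N)},
            source=getattr(row, "source", "RNA"),
        )


def read_alignments_to_pileup(
    path: str | Path,
    sample: str,
    region: tuple[str, int, int] | None = None,
    min_base_q: int = 25,
    min_map_q: int = 25,
    drop_multihit: bool = True,
    drop_duplicates: bool = True,
    fasta: str | Path | None = None,
    source: str = "RNA",
) -> Iterator[PileupColumn]:
    """Stream PileupColumns from an indexed BAM/CRAM.

    Bases below ``min_base_q`` are not tallied. Reads are excluded when
    their mapping quality is below ``min_map_q``, when they carry
    secondary/supplementary flags (``drop_multihit``), or when they are
    duplicate-flagged (``drop_duplicates``).
    """
    af = pysam.AlignmentFile(str(path))
    if not af.has_index():
        raise FormatError(f"{path} is not indexed; sort and index the alignments first")
    kwargs = {}
    if region is not None:
        kwargs = {"contig": region[0], "start": region[1], "stop": region[2],
                  "truncate": True}
    ref_fa = pysam.FastaFile(str(fasta)) if fasta else None
    n_cols = 0
    # base-quality filtering is done explicitly below; keep the engine permissive
    for col in af.pileup(min_base_quality=0, stepper="nofilter", **kwargs):
        counts = {b: 0 for b in ("A", "C", "G", "T", "N")}
        for pr in col.pileups:
            aln = pr.alignment
            if aln.mapping_quality < min_map_q:
                continue
            if drop_multihit and (aln.is_secondary or aln.is_supplementary):
                continue
            if drop_duplicates and aln.is_duplicate:
                continue
            if pr.is_del or pr.is_refskip or pr.query_position is None:
                continue
            if aln.query_qualities is not None and aln.query_qualities[pr.query_position] < min_base_q:
                continue
            base = aln.query_sequence[pr.query_position].upper()
            if base in counts:
                counts[base] += 1
        if sum(counts.values()) == 0:
            continue
        ref = "N"
        if ref_fa is not None:
            ref = ref_fa.fetch(col.reference_name, col.reference_pos,
                               col.reference_pos + 1).upper()
        n_cols += 1
        yield PileupColumn(
            contig=col.reference_name,
            pos0=col.reference_pos,
            ref=ref,
            sample=sample,
            counts=counts,
            source=source,
        )
    log.info("pileup %s: %d non-empty columns", path, n_cols)


def columns_to_frame(cols: Iterable[PileupColumn], source: str = "RNA") -> pd.DataFrame:
    rows = [
        {
            "contig": c.contig, "pos0": c.pos0, "ref": c.ref, "sample": c.sample,
            "A": c.counts.get("A", 0), "C": c.counts.get("C", 0),
            "G": c.counts.get("G", 0), "T": c.counts.get("T", 0),
            "N": c.counts.get("N", 0),
        }
        for c in cols
    ]
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    df["source"] = source
    return df
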