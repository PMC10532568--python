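"""BED12-like table for classified splicing events.

Coordinates are 0-based half-open per the BED standard; minus-strand
events keep ascending coordinates. Columns 1-12 follow BED12; extra
columns carry the event type, gene id, and per-stage PSI.
"""
from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from fdrm.core_io.design import StageDesign
    from fdrm.splicing import ASEvent

BED_CORE = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def events_to_table(events: list["ASEvent"], design: "StageDesign") -> pd.DataFrame:
    rows = []
    for ev in events:
        start, end = ev.region
        row = {
            "chrom": ev.contig,
            "chromStart": start,
            "chromEnd": end,
            "name": ev.event_id,
            "score": 0,
            "strand": ev.strand,
            "thickStart": start,
            "thickEnd": end,
            "itemRgb": "0",
            "blockCount": 1,
            "blockSizes": str(end - start),
            "blockStarts": "0",
            "as_type": ev.as_type,
            "gene_id": ev.gene_id,
        }
        for stage in design.stages:
            psi = ev.psi.get(stage)
            row[f"psi_{stage}"] = "" if psi is None else round(psi, 6)
        rows.append(row)
    cols = BED_CORE + ["as_type", "gene_id"] + [f"psi_{s}" for s in design.stages]
    return pd.DataFrame(rows, columns=cols)


def write_as_events(events: list["ASEvent"], path: str | Path, design: "StageDesign") -> None:
    events_to_table(events, design).to_csv(path, sep="\t", index=False)


def read_as_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
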