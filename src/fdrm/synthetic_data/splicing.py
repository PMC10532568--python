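"""Junction/region evidence simulator with planted splicing events.

Each planted event reproduces the evidence pattern its type produces in
real data: inclusion/exclusion junction reads are drawn binomially around
the per-stage true PSI at the requested coverage; intron-retention and
terminal-exon events additionally emit coverage regions. All annotated
junctions of every gene also receive constitutive baseline reads.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fdrm.core_io.design import StageDesign
from fdrm.core_io.junctions import JUNCTION_COLUMNS, REGION_COLUMNS
from fdrm.core_io.models import GeneModel
from fdrm.synthetic_data.manifest import TruthManifest

log = logging.getLogger(__name__)

PLANTABLE_TYPES = ("IR", "A5SS", "A3SS", "CE", "MXE", "AFE", "ALE", "complex")

_SS_SHIFT = 9       # alt splice-site offset into the intron
_NOVEL_EXON = 20    # novel terminal exon length
_CLEAN = 6


def _needs(as_type: str) -> tuple[int, int]:
    """(min exons, min intron length) required to plant a type."""
    return {
        "IR": (2, 10), "A5SS": (2, 2 * _SS_SHIFT + 10), "A3SS": (2, 2 * _SS_SHIFT + 10),
        "CE": (3, 10), "MXE": (4, 10),
        "AFE": (2, _NOVEL_EXON + 2 * _SS_SHIFT), "ALE": (2, _NOVEL_EXON + 2 * _SS_SHIFT),
        "complex": (2, 10),
    }[as_type]


def _stage_psi(rng: np.random.Generator, design: StageDesign) -> dict[str, float]:
    base = rng.uniform(0.3, 0.7)
    return {
        s: float(np.clip(base + rng.normal(0.0, 0.15), 0.05, 0.95))
        for s in design.stages
    }


class _Evidence:
    def __init__(self) -> None:
        self.junctions: list[dict] = []
        self.regions: list[dict] = []

    def junc(self, contig: str, d0: int, a0: int, sample: str, reads: int,
             clean: int = _CLEAN) -> None:
        if reads > 0:
            self.junctions.append({
                "contig": contig, "donor0": d0, "acceptor0": a0,
                "sample": sample, "reads": int(reads), "clean_overhang_bases": clean,
            })

    def region(self, contig: str, s0: int, e0: int, sample: str, cov: float) -> None:
        if cov > 0:
            self.regions.append({
                "contig": contig, "start0": s0, "end0": e0,
                "sample": sample, "mean_cov": float(cov),
            })


def _plant_event(
    ev: _Evidence,
    rng: np.random.Generator,
    gene: GeneModel,
    as_type: str,
    design: StageDesign,
    coverage: int,
    psi: dict[str, float],
) -> tuple[tuple[int, int], set[tuple[int, int]]]:
    """Emit evidence for one event; returns (region, junctions owned by the event)."""
    introns = gene.introns
    exons = gene.exons
    contig = gene.contig
    # genomic side being varied: A5SS varies the transcript-5' side
    left_side = {"A5SS": gene.strand == "+", "A3SS": gene.strand == "-",
                 "AFE": gene.strand == "+", "ALE": gene.strand == "-"}

    def draws() -> dict[str, tuple[int, int]]:
        out = {}
        for stage in design.stages:
            for rep in design.replicates[stage]:
                total = max(int(rng.poisson(coverage)), 20)
                n_inc = int(rng.binomial(total, psi[stage]))
                out[rep] = (n_inc, total - n_inc)
        return out

    counts = draws()

    if as_type == "IR":
        idx = int(rng.integers(0, len(introns)))
        d0, a0 = introns[idx]
        for rep, (inc, exc) in counts.items():
            ev.region(contig, d0, a0, rep, inc)
            ev.junc(contig, d0, a0, rep, exc)
        return (d0, a0), {(d0, a0)}

    if as_type in {"A5SS", "A3SS"}:
        idx = int(rng.integers(0, len(introns)))
        d0, a0 = introns[idx]
        if left_side[as_type]:
            novel = (d0 + _SS_SHIFT, a0)  # donor moved into the intron (exon extension)
            region = (d0, d0 + _SS_SHIFT)
        else:
            novel = (d0, a0 - _SS_SHIFT)
            region = (a0 - _SS_SHIFT, a0)
        for rep, (inc, exc) in counts.items():
            ev.junc(contig, *novel, rep, inc)       # extension isoform
            ev.junc(contig, d0, a0, rep, exc)       # annotated isoform
        return region, {novel, (d0, a0)}

    if as_type == "CE":
        idx = int(rng.integers(0, len(exons) - 2))  # cassette = exon idx+1
        j1, j2 = introns[idx], introns[idx + 1]
        skip = (j1[0], j2[1])
        for rep, (inc, exc) in counts.items():
            ev.junc(contig, *j1, rep, inc)
            ev.junc(contig, *j2, rep, inc)
            ev.junc(contig, *skip, rep, exc)
        return exons[idx + 1], {j1, j2, skip}

    if as_type == "MXE":
        idx = int(rng.integers(0, len(exons) - 3))  # exons idx+1, idx+2 exclusive
        j_ax, j_xy, j_yb = introns[idx], introns[idx + 1], introns[idx + 2]
        skip_y = (j_xy[0], j_yb[1])     # X -> B
        skip_x = (j_ax[0], j_xy[1])     # A -> Y
        for rep, (inc, exc) in counts.items():
            ev.junc(contig, *j_ax, rep, inc)
            ev.junc(contig, *skip_y, rep, inc)
            ev.junc(contig, *skip_x, rep, exc)
            ev.junc(contig, *j_yb, rep, exc)
        region = (exons[idx + 1][0], exons[idx + 2][1])
        return region, {j_ax, j_xy, j_yb, skip_x, skip_y}

    if as_type in {"AFE", "ALE"}:
        if left_side[as_type]:
            d0, a0 = introns[0]
            novel_exon = (d0 + _SS_SHIFT, d0 + _SS_SHIFT + _NOVEL_EXON)
            novel_j = (novel_exon[1], a0)
        else:
            d0, a0 = introns[-1]
            novel_exon = (a0 - _SS_SHIFT - _NOVEL_EXON, a0 - _SS_SHIFT)
            novel_j = (d0, novel_exon[0])
        for rep, (inc, exc) in counts.items():
            ev.junc(contig, d0, a0, rep, inc)       # annotated terminal exon
            ev.junc(contig, *novel_j, rep, exc)
            ev.region(contig, *novel_exon, rep, exc)
        return novel_exon, {(d0, a0), novel_j}

    # complex: junction from mid-exon to mid-exon, paired against the
    # annotated junction it straddles
    idx = int(rng.integers(0, len(introns)))
    e_up, e_dn = exons[idx], exons[idx + 1]
    novel = ((e_up[0] + e_up[1]) // 2, (e_dn[0] + e_dn[1]) // 2)
    ann = introns[idx]
    for rep, (inc, exc) in counts.items():
        ev.junc(contig, *ann, rep, inc)
        ev.junc(contig, *novel, rep, exc)
    return novel, {ann, novel}


def simulate_splicing(
    gene_models: list[GeneModel],
    design: StageDesign,
    n_events_per_type: int = 2,
    coverage: int = 120,
    seed: int = 0,
    types: tuple[str, ...] = PLANTABLE_TYPES,
    baseline_coverage: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Returns (junction evidence, region evidence, manifest).

    One event is planted per gene; genes lacking the exon/intron geometry
    for a type are skipped with a warning. All annotated junctions not
    owned by an event get constitutive baseline reads.
    """
    rng = np.random.default_rng(seed)
    baseline = coverage if baseline_coverage is None else baseline_coverage
    ev = _Evidence()
    manifest = TruthManifest(seed=seed)
    multi = [m for m in gene_models if len(m.exons) >= 2]
    order = list(rng.permutation(len(multi)))
    used: set[str] = set()
    owned: dict[str, set[tuple[int, int]]] = {}

    for as_type in types:
        n_planted = 0
        min_ex, min_intron = _needs(as_type)
        for gi in order:
            if n_planted >= n_events_per_type:
                break
            gene = multi[gi]
            if gene.gene_id in used or len(gene.exons) < min_ex:
                continue
            if any(a - d < min_intron for d, a in gene.introns):
                continue
            psi = _stage_psi(rng, design)
            region, event_juncs = _plant_event(ev, rng, gene, as_type, design,
                                               coverage, psi)
            used.add(gene.gene_id)
            owned[gene.gene_id] = event_juncs
            manifest.planted_as.append({
                "event_id": f"{gene.gene_id}:{as_type}:{region[0]}-{region[1]}",
                "gene_id": gene.gene_id,
                "as_type": as_type,
                "region": list(region),
                "psi": psi,
            })
            n_planted += 1
        if n_planted < n_events_per_type:
            log.warning("only planted %d/%d events of type %s",
                        n_planted, n_events_per_type, as_type)

    # constitutive baseline on junctions not owned by an event (the silent
    # middle junction of an MXE is owned, so it stays silent)
    for gene in gene_models:
        event_juncs = owned.get(gene.gene_id, set())
        for junc in gene.introns:
            if junc in event_juncs:
                continue
            for rep in design.samples:
                ev.junc(gene.contig, *junc, rep, int(rng.poisson(baseline)))

    junctions = pd.DataFrame(ev.junctions, columns=JUNCTION_COLUMNS)
    regions = pd.DataFrame(ev.regions, columns=REGION_COLUMNS)
    return junctions, regions, manifest
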