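"""Alternative-splicing event classification, filtering, PSI, differential tests.

Events are inferred by comparing observed junction/coverage evidence against
the annotated gene model. Eight types are assigned: IR (intron retention),
A5SS/A3SS (alternative 5'/3' splice site, named on the transcript strand),
CE (cassette exon), MXE (mutually exclusive exons), AFE/ALE (alternative
first/last exon, requiring a coverage-supported novel exon disjoint from the
annotated ones), and complex for anything else.

Evidence thresholds: a junction needs >= 10 pooled reads in some stage, the
event > 25 total reads, and the minor isoform >= 5 reads at > 5% abundance;
junctions whose alignment overhang is not clean within 6 bases are dropped
before counting. Differential calls require |dPSI| > 0.1, Fisher p < 0.05
and BH FDR < 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fdrm.core_io.config import SplicingConfig
from fdrm.core_io.design import StageDesign
from fdrm.core_io.models import GeneModel, Interval

log = logging.getLogger(__name__)

AS_TYPES = ("IR", "A5SS", "A3SS", "CE", "MXE", "AFE", "ALE", "complex")

Junction = tuple[int, int]  # (donor0, acceptor0); intron = [donor0, acceptor0)


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    contig: str
    strand: str
    as_type: str
    region: Interval
    inc_junctions: list[Junction] = field(default_factory=list)
    exc_junctions: list[Junction] = field(default_factory=list)
    inclusion_counts: dict[str, float] = field(default_factory=dict)
    exclusion_counts: dict[str, float] = field(default_factory=dict)
    n_inc: int = 1  # distinct supporting junction positions (effective length)
    n_exc: int = 1
    intron: Interval | None = None  # retained intron, IR only
    psi: dict[str, float | None] = field(default_factory=dict)

    def pooled(self, samples: list[str]) -> tuple[float, float]:
        inc = sum(self.inclusion_counts.get(s, 0.0) for s in samples)
        exc = sum(self.exclusion_counts.get(s, 0.0) for s in samples)
        return inc, exc


@dataclass
class DifferentialSplicingResult:
    event_id: str
    stage_a: str
    stage_b: str
    delta_psi: float | None
    pvalue: float
    fdr: float = float("nan")
    significant: bool = False
    testable: bool = True


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _assign_gene(models: list[GeneModel], contig: str, lo: int, hi: int) -> GeneModel | None:
    """The unique gene whose span contains [lo, hi); None if 0 or >1 match."""
    hits = [m for m in models if m.contig == contig and m.start <= lo and hi <= m.end]
    if len(hits) != 1:
        return None
    return hits[0]


def _region_cov(
    regions: pd.DataFrame, contig: str, iv: Interval, min_span: float = 0.0
) -> dict[str, float]:
    """Per-sample overlap-weighted mean coverage over an interval.

    Returns nothing unless the regions jointly cover at least ``min_span``
    of the interval (guards IR calls against short intra-intronic features
    such as novel terminal exons).
    """
    lo, hi = iv
    sub = regions[(regions["contig"] == contig)
                  & (regions["end0"] > lo) & (regions["start0"] < hi)]
    out: dict[str, float] = {}
    if sub.empty:
        return out
    covered = np.zeros(hi - lo, dtype=bool)
    for s0, e0 in zip(sub["start0"], sub["end0"]):
        covered[max(s0 - lo, 0): max(min(e0, hi) - lo, 0)] = True
    if covered.mean() < min_span:
        return out
    for sample, grp in sub.groupby("sample"):
        ov = np.minimum(grp["end0"], hi) - np.maximum(grp["start0"], lo)
        out[str(sample)] = float(np.sum(grp["mean_cov"] * ov) / np.sum(ov))
    return out


def _novel_exon_at(regions: pd.DataFrame, gene: GeneModel, *, start: int | None = None,
                   end: int | None = None) -> Interval | None:
    """Coverage-supported region anchored at a splice end, disjoint from annotated exons."""
    sub = regions[regions["contig"] == gene.contig]
    if start is not None:
        sub = sub[sub["start0"] == start]
    if end is not None:
        sub = sub[sub["end0"] == end]
    for row in sub.itertuples(index=False):
        iv = (int(row.start0), int(row.end0))
        if all(iv[1] <= xs or iv[0] >= xe for xs, xe in gene.exons):
            return iv
    return None


def classify_as_events(
    gene_models: list[GeneModel],
    junctions: pd.DataFrame,
    exonic_region_counts: pd.DataFrame | None = None,
    config: SplicingConfig | None = None,
) -> list[ASEvent]:
    """Detect and type splicing alternatives from junction/region evidence.

    Junctions that do not fall inside exactly one gene are dropped (and
    logged): intergenic and gene-overlapping evidence is excluded.
    """
    config = config or SplicingConfig()
    regions = exonic_region_counts if exonic_region_counts is not None else pd.DataFrame(
        columns=["contig", "start0", "end0", "sample", "mean_cov"]
    )
    clean = junctions[junctions["clean_overhang_bases"] >= config.min_clean_overhang]
    n_dropped_dirty = len(junctions) - len(clean)
    if n_dropped_dirty:
        log.info("dropped %d junction rows without clean overhang", n_dropped_dirty)

    # per-junction per-sample read counts
    grouped = clean.groupby(["contig", "donor0", "acceptor0", "sample"])["reads"].sum()
    pooled = clean.groupby(["contig", "donor0", "acceptor0"])["reads"].sum()

    by_gene: dict[str, list[Junction]] = {}
    gene_by_id = {m.gene_id: m for m in gene_models}
    n_unassigned = 0
    for (contig, d0, a0) in pooled.index:
        gene = _assign_gene(gene_models, str(contig), int(d0), int(a0))
        if gene is None:
            n_unassigned += 1
            continue
        by_gene.setdefault(gene.gene_id, []).append((int(d0), int(a0)))
    if n_unassigned:
        log.info("dropped %d junctions outside a unique gene", n_unassigned)

    events: list[ASEvent] = []
    for gene_id, observed in sorted(by_gene.items()):
        gene = gene_by_id[gene_id]
        events.extend(_classify_gene(gene, sorted(set(observed)), grouped, pooled, regions))
    return events


def _junction_counts(gene: GeneModel, juncs: list[Junction], grouped: pd.Series) -> dict[str, float]:
    out: dict[str, float] = {}
    for d0, a0 in juncs:
        try:
            sub = grouped.loc[(gene.contig, d0, a0)]
        except KeyError:
            continue
        for sample, reads in sub.items():
            out[sample] = out.get(sample, 0.0) + float(reads)
    return out


def _pooled_reads(gene: GeneModel, junc: Junction, pooled: pd.Series) -> float:
    try:
        return float(pooled.loc[(gene.contig, junc[0], junc[1])])
    except KeyError:
        return 0.0


def _classify_gene(
    gene: GeneModel,
    observed: list[Junction],
    grouped: pd.Series,
    pooled: pd.Series,
    regions: pd.DataFrame,
) -> list[ASEvent]:
    annotated = gene.introns
    ann_set = set(annotated)
    donors = {e: i for i, (_, e) in enumerate(gene.exons)}      # exon end -> exon index
    acceptors = {s: i for i, (s, _) in enumerate(gene.exons)}   # exon start -> exon index
    ann_by_donor = {d: (d, a) for d, a in annotated}
    ann_by_acceptor = {a: (d, a) for d, a in annotated}
    events: list[ASEvent] = []

    def mk(as_type: str, region: Interval, inc: list[Junction], exc: list[Junction],
           inc_counts: dict[str, float] | None = None, intron: Interval | None = None) -> ASEvent:
        ev = ASEvent(
            event_id=f"{gene.gene_id}:{as_type}:{region[0]}-{region[1]}",
            gene_id=gene.gene_id,
            contig=gene.contig,
            strand=gene.strand,
            as_type=as_type,
            region=region,
            inc_junctions=inc,
            exc_junctions=exc,
            n_inc=max(len(inc), 1),
            n_exc=max(len(exc), 1),
            intron=intron,
        )
        ev.inclusion_counts = inc_counts if inc_counts is not None else _junction_counts(gene, inc, grouped)
        ev.exclusion_counts = _junction_counts(gene, exc, grouped)
        return ev

    # --- intron retention: annotated junction observed + intronic coverage
    for idx, intron in enumerate(annotated):
        if intron not in observed:
            continue
        cov = _region_cov(regions, gene.contig, intron, min_span=0.8)
        if cov and sum(cov.values()) > 0:
            events.append(mk("IR", intron, inc=[], exc=[intron],
                             inc_counts=cov, intron=intron))

    novel = [j for j in observed if j not in ann_set]
    skips: dict[tuple[int, int], Junction] = {}
    rest: list[Junction] = []
    for d0, a0 in novel:
        i = donors.get(d0)
        j = acceptors.get(a0)
        if i is not None and j is not None and j > i + 1:
            skips[(i, j)] = (d0, a0)
        else:
            rest.append((d0, a0))

    # --- mutually exclusive exons: adjacent single-exon skips, no junction between
    consumed: set[tuple[int, int]] = set()
    for (i, j), skip_x in sorted(skips.items()):
        if j != i + 2 or (i, j) in consumed:
            continue
        partner = (i + 1, i + 3)
        if partner in skips and partner not in consumed:
            between = annotated[i + 1]  # junction joining the two middle exons
            if _pooled_reads(gene, between, pooled) == 0:
                skip_y = skips[partner]
                exon_x, exon_y = gene.exons[i + 1], gene.exons[i + 2]
                events.append(mk(
                    "MXE", (exon_x[0], exon_y[1]),
                    inc=[annotated[i], skip_y],      # isoform keeping the upstream exon
                    exc=[skip_x, annotated[i + 2]],  # isoform keeping the downstream exon
                ))
                consumed.update({(i, j), partner})

    # --- cassette exon / multi-exon skip
    for (i, j), skip in sorted(skips.items()):
        if (i, j) in consumed:
            continue
        if j == i + 2:
            exon = gene.exons[i + 1]
            events.append(mk("CE", exon, inc=[annotated[i], annotated[i + 1]], exc=[skip]))
        else:
            inc = annotated[i:j]
            events.append(mk("complex", skip, inc=inc, exc=[skip]))

    # --- junction pairs sharing one end, terminal exons, leftovers
    for d0, a0 in rest:
        ann = ann_by_donor.get(d0)
        if ann is not None and ann[1] != a0:
            novel_exon = _novel_exon_at(regions, gene, start=a0)
            if novel_exon is not None:
                as_type = "ALE" if gene.strand == "+" else "AFE"
                events.append(mk(as_type, novel_exon, inc=[ann], exc=[(d0, a0)]))
            else:
                as_type = "A3SS" if gene.strand == "+" else "A5SS"
                lo, hi = sorted((a0, ann[1]))
                inc, exc = ((d0, a0), ann) if a0 < ann[1] else (ann, (d0, a0))
                events.append(mk(as_type, (lo, hi), inc=[inc], exc=[exc]))
            continue
        ann = ann_by_acceptor.get(a0)
        if ann is not None and ann[0] != d0:
            novel_exon = _novel_exon_at(regions, gene, end=d0)
            if novel_exon is not None:
                as_type = "AFE" if gene.strand == "+" else "ALE"
                events.append(mk(as_type, novel_exon, inc=[ann], exc=[(d0, a0)]))
            else:
                as_type = "A5SS" if gene.strand == "+" else "A3SS"
                lo, hi = sorted((d0, ann[0]))
                inc, exc = ((d0, a0), ann) if d0 > ann[0] else (ann, (d0, a0))
                events.append(mk(as_type, (lo, hi), inc=[inc], exc=[exc]))
            continue
        # neither end matches annotated structure
        overlapping = [iv for iv in annotated if iv[0] < a0 and iv[1] > d0]
        events.append(mk("complex", (d0, a0), inc=overlapping, exc=[(d0, a0)]))

    return events


# ---------------------------------------------------------------------------
# filtering and PSI
# ---------------------------------------------------------------------------


def _stage_pass(inc: float, exc: float, n_inc: int, n_exc: int, cfg: SplicingConfig) -> bool:
    total = inc + exc
    if total <= cfg.min_total_cov:
        return False
    if max(inc / n_inc, exc / n_exc) < cfg.min_junction_reads:
        return False
    minor = min(inc, exc)
    if minor < cfg.rare_min_expr:
        return False
    if minor / total <= cfg.rare_min_ratio:
        return False
    return True


def filter_as_events(
    events: list[ASEvent],
    design: StageDesign,
    config: SplicingConfig | None = None,
) -> list[ASEvent]:
    """Keep events passing junction-support/coverage/rare-isoform rules in >= 1 stage."""
    cfg = config or SplicingConfig()
    kept = []
    for ev in events:
        for stage in design.stages:
            inc, exc = ev.pooled(design.replicates[stage])
            if _stage_pass(inc, exc, ev.n_inc, ev.n_exc, cfg):
                kept.append(ev)
                break
    return kept


def compute_psi(event: ASEvent, stage: str, design: StageDesign) -> float | None:
    """Pooled per-stage PSI with effective-length normalization.

    Each side's raw count is divided by its number of distinct supporting
    junction positions before the inclusion ratio. Undefined (None) when
    the denominator is zero.
    """
    design.check_stage(stage)
    inc, exc = event.pooled(design.replicates[stage])
    inc_n, exc_n = inc / event.n_inc, exc / event.n_exc
    denom = inc_n + exc_n
    if denom <= 0:
        return None
    return inc_n / denom


def compute_psi_matrix(events: list[ASEvent], design: StageDesign) -> pd.DataFrame:
    rows = {}
    for ev in events:
        ev.psi = {stage: compute_psi(ev, stage, design) for stage in design.stages}
        rows[ev.event_id] = {s: (np.nan if v is None else v) for s, v in ev.psi.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=design.stages)


# ---------------------------------------------------------------------------
# differential splicing
# ---------------------------------------------------------------------------


def differential_splicing(
    event: ASEvent, stage_a: str, stage_b: str, design: StageDesign
) -> DifferentialSplicingResult:
    """Two-sided Fisher exact test on the pooled 2x2 inclusion/exclusion table."""
    psi_a = compute_psi(event, stage_a, design)
    psi_b = compute_psi(event, stage_b, design)
    if psi_a is None or psi_b is None:
        return DifferentialSplicingResult(event.event_id, stage_a, stage_b,
                                          delta_psi=None, pvalue=float("nan"),
                                          testable=False)
    inc_a, exc_a = event.pooled(design.replicates[stage_a])
    inc_b, exc_b = event.pooled(design.replicates[stage_b])
    table = np.round([[inc_a, exc_a], [inc_b, exc_b]]).astype(int)
    _, pval = stats.fisher_exact(table, alternative="two-sided")
    return DifferentialSplicingResult(event.event_id, stage_a, stage_b,
                                      delta_psi=psi_b - psi_a, pvalue=float(pval))


def differential_splicing_table(
    events: list[ASEvent],
    design: StageDesign,
    pairs: list[tuple[str, str]] | None = None,
    config: SplicingConfig | None = None,
) -> pd.DataFrame:
    """All per-pair tests with BH correction within each comparison."""
    cfg = config or SplicingConfig()
    pairs = pairs or design.stage_pairs()
    rows = []
    for a, b in pairs:
        results = [differential_splicing(ev, a, b, design) for ev in events]
        testable = [r for r in results if r.testable]
        if testable:
            adj = multipletests([r.pvalue for r in testable], method="fdr_bh")[1]
            for r, q in zip(testable, adj):
                r.fdr = float(q)
                r.significant = (
                    abs(r.delta_psi) > cfg.delta_psi
                    and r.pvalue < cfg.pvalue
                    and r.fdr < cfg.fdr
                )
        rows.extend(results)
    return pd.DataFrame(
        [
            {"event_id": r.event_id, "stage_a": r.stage_a, "stage_b": r.stage_b,
             "delta_psi": np.nan if r.delta_psi is None else r.delta_psi,
             "pvalue": r.pvalue, "fdr": r.fdr, "significant": r.significant,
             "testable": r.testable}
            for r in rows
        ]
    )


def process_specific_events(diff: pd.DataFrame, design: StageDesign) -> dict[str, set[str]]:
    """Events significant in comparisons of exactly one developmental process."""
    proc_hits: dict[str, set[str]] = {}
    for process in design.processes:
        pairs = {tuple(sorted(p)) for p in design.stage_pairs(process)}
        mask = diff.apply(
            lambda r: r["significant"] and tuple(sorted((r["stage_a"], r["stage_b"]))) in pairs,
            axis=1,
        ) if len(diff) else pd.Series(dtype=bool)
        proc_hits[process] = set(diff.loc[mask, "event_id"]) if len(diff) else set()
    specific: dict[str, set[str]] = {}
    all_events = set().union(*proc_hits.values()) if proc_hits else set()
    for ev in all_events:
        procs = {p for p, evs in proc_hits.items() if ev in evs}
        if len(procs) == 1:
            specific[ev] = procs
    return specific
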