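"""RNA-editing calling from paired DNA/RNA pileup evidence.

A site is called when, per replicate, the RNA pileup shows an alternative
base with >= 3 supporting reads, >= 3% frequency, and >= 10 total coverage;
the DNA pileup at the position is deep enough (>= 10 by default) and fully
reference (strictest reading of "not supported by or with changes in
DNA-seq"); the position is farther than 4 nt from any annotated or observed
splice boundary; and the candidate recurs in >= 2 replicates of at least
one stage. Types are named on the transcript sense strand (A->G is
reported as A-to-I(G), T->C as U-to-C, ...); intergenic sites use the plus
strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fdrm.core_io.config import EditingConfig
from fdrm.core_io.design import StageDesign
from fdrm.core_io.genome import GenomeRef
from fdrm.core_io.models import GeneModel
from fdrm.core_io.pileup import BASES
from fdrm.errors import ConsistencyError, FdrmError

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class EditingSite:
    contig: str
    pos0: int
    ref_plus: str
    alt_plus: str
    strand: str  # transcript strand; '+' for intergenic sites
    ed_type: str
    levels: dict[str, float] = field(default_factory=dict)        # sample -> level
    support: dict[str, tuple[int, int]] = field(default_factory=dict)  # sample -> (edited, depth)
    stages_present: set[str] = field(default_factory=set)
    gene_id: str | None = None
    feature: str | None = None
    effect: str | None = None
    ambiguous_strand: bool = False

    @property
    def ref_sense(self) -> str:
        return _COMP[self.ref_plus] if self.strand == "-" else self.ref_plus

    @property
    def alt_sense(self) -> str:
        return _COMP[self.alt_plus] if self.strand == "-" else self.alt_plus

    def stage_level(self, stage: str, design: StageDesign) -> float | None:
        """Mean level over the stage's replicates that carry the site."""
        vals = [self.levels[s] for s in design.replicates[stage] if s in self.levels]
        return sum(vals) / len(vals) if vals else None


def classify_editing_type(ref_plus: str, alt_plus: str, strand: str) -> str:
    """Editing-type label in transcript orientation (RNA alphabet, T->U)."""
    if ref_plus == alt_plus:
        raise FdrmError("ref and alt bases are identical")
    ref, alt = (ref_plus, alt_plus) if strand == "+" else (_COMP[ref_plus], _COMP[alt_plus])
    if ref == "A" and alt == "G":
        return "A-to-I(G)"
    u = {"T": "U"}
    return f"{u.get(ref, ref)}-to-{u.get(alt, alt)}"


def editing_level(edited_reads: int, depth: int) -> float | None:
    """edited/depth; undefined (None) at zero depth, never coerced to 0."""
    if depth <= 0:
        return None
    return edited_reads / depth


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------


def _splice_exclusion_set(
    gene_models: list[GeneModel],
    observed_junctions: pd.DataFrame | None,
    window: int,
) -> set[tuple[str, int]]:
    """Positions within `window` nt of any annotated or observed splice boundary."""
    excl: set[tuple[str, int]] = set()

    def add(contig: str, boundary: int) -> None:
        for p in range(boundary - window, boundary + window + 1):
            excl.add((contig, p))

    for m in gene_models:
        for b in m.splice_boundaries():
            add(m.contig, b)
    if observed_junctions is not None:
        for row in observed_junctions.itertuples(index=False):
            add(str(row.contig), int(row.donor0))
            add(str(row.contig), int(row.acceptor0) - 1)
    return excl


def _rna_candidates(rna: pd.DataFrame, cfg: EditingConfig) -> pd.DataFrame:
    """Rule (ii) per pileup row: alt reads >= 3, freq >= 3%, depth >= 10."""
    depth = rna[list(BASES)].sum(axis=1)
    rows = []
    for (_, row), dp in zip(rna.iterrows(), depth):
        if dp < cfg.min_depth:
            continue
        ref = row["ref"]
        for base in BASES:
            if base == ref:
                continue
            alt_n = int(row[base])
            if alt_n >= cfg.min_alt_reads and alt_n / dp >= cfg.min_alt_freq:
                rows.append({
                    "contig": row["contig"], "pos0": int(row["pos0"]), "ref": ref,
                    "sample": row["sample"], "alt": base,
                    "alt_reads": alt_n, "depth": int(dp),
                })
    return pd.DataFrame(rows, columns=["contig", "pos0", "ref", "sample",
                                       "alt", "alt_reads", "depth"])


def _dna_clean_positions(dna: pd.DataFrame, cfg: EditingConfig) -> set[tuple[str, int]]:
    """Positions with DNA depth >= floor and alt fraction <= allowed (default 0)."""
    ok: set[tuple[str, int]] = set()
    for row in dna.itertuples(index=False):
        if row.ref not in BASES:
            continue
        depth = row.A + row.C + row.G + row.T
        if depth < cfg.dna_min_depth:
            continue
        alt = depth - getattr(row, row.ref)
        if depth > 0 and alt / depth <= cfg.dna_max_alt_frac:
            ok.add((row.contig, int(row.pos0)))
    return ok


def _gene_at(gene_models: list[GeneModel], contig: str, pos0: int) -> tuple[GeneModel | None, bool]:
    hits = [m for m in gene_models if m.contig == contig and m.contains(pos0)]
    if not hits:
        return None, False
    strands = {m.strand for m in hits}
    return hits[0], len(strands) > 1


def call_editing_sites(
    dna_pileup: pd.DataFrame,
    rna_pileup: pd.DataFrame,
    gene_models: list[GeneModel],
    design: StageDesign,
    observed_junctions: pd.DataFrame | None = None,
    genome: GenomeRef | None = None,
    config: EditingConfig | None = None,
) -> list[EditingSite]:
    """Apply the DNA/RNA comparison rules and return surviving sites.

    In ``per_replicate`` mode (default) candidates are called per replicate
    and a site is present in a stage when >= 2 of its replicates carry the
    same substitution; in ``merged`` mode replicate tallies are pooled per
    stage before the threshold rule and presence requires candidate support
    in >= 2 individual replicates as well.
    """
    cfg = config or EditingConfig()
    if genome is not None:
        for row in pd.concat([dna_pileup, rna_pileup]).itertuples(index=False):
            ref = genome.fetch(row.contig, int(row.pos0), int(row.pos0) + 1)
            if ref != row.ref:
                raise ConsistencyError(
                    f"{row.contig}:{row.pos0}: pileup ref {row.ref} != genome {ref}")

    excl = _splice_exclusion_set(gene_models, observed_junctions, cfg.splice_exclusion_nt)
    dna_ok = _dna_clean_positions(dna_pileup, cfg)

    if cfg.mode == "merged":
        merged = rna_pileup.copy()
        merged["stage"] = merged["sample"].map(design.stage_of)
        pooled = merged.groupby(["contig", "pos0", "ref", "stage"], as_index=False)[
            ["A", "C", "G", "T", "N"]].sum()
        pooled = pooled.rename(columns={"stage": "sample"})
        stage_cand = _rna_candidates(pooled, cfg)
        allowed = {(r.contig, r.pos0, r.alt, r.sample)
                   for r in stage_cand.itertuples(index=False)}
        cand = _rna_candidates_lenient(rna_pileup, cfg)
        keep = np.fromiter(
            ((r.contig, r.pos0, r.alt, design.stage_of(r.sample)) in allowed
             for r in cand.itertuples(index=False)),
            dtype=bool, count=len(cand))
        cand = cand.loc[keep]
    else:
        cand = _rna_candidates(rna_pileup, cfg)

    n0 = len(cand)
    keep = np.fromiter(((c, p) in dna_ok for c, p in zip(cand["contig"], cand["pos0"])),
                       dtype=bool, count=len(cand))
    cand = cand.loc[keep]
    n1 = len(cand)
    keep = np.fromiter(((c, p) not in excl for c, p in zip(cand["contig"], cand["pos0"])),
                       dtype=bool, count=len(cand))
    cand = cand.loc[keep]
    log.info("editing candidates: %d raw, %d after DNA rule, %d after splice rule",
             n0, n1, len(cand))

    sites: list[EditingSite] = []
    for (contig, pos0, ref, alt), grp in cand.groupby(["contig", "pos0", "ref", "alt"]):
        stage_reps: dict[str, list] = {}
        for row in grp.itertuples(index=False):
            stage_reps.setdefault(design.stage_of(row.sample), []).append(row)
        present = {st for st, rows in stage_reps.items() if len(rows) >= cfg.min_replicates}
        if not present:
            continue
        gene, ambiguous = _gene_at(gene_models, str(contig), int(pos0))
        strand = gene.strand if gene is not None else "+"
        site = EditingSite(
            contig=str(contig), pos0=int(pos0), ref_plus=str(ref), alt_plus=str(alt),
            strand=strand,
            ed_type=classify_editing_type(str(ref), str(alt), strand),
            stages_present=present,
            gene_id=gene.gene_id if gene is not None else None,
            ambiguous_strand=ambiguous,
        )
        for st in present:
            for row in stage_reps[st]:
                site.support[row.sample] = (int(row.alt_reads), int(row.depth))
                site.levels[row.sample] = row.alt_reads / row.depth
        sites.append(site)
    sites.sort(key=lambda s: (s.contig, s.pos0, s.alt_plus))
    return sites


def _rna_candidates_lenient(rna: pd.DataFrame, cfg: EditingConfig) -> pd.DataFrame:
    """Any alt-supported row (>=1 read); used to collect per-replicate support
    after merged-mode stage-level thresholds have been applied."""
    relaxed = EditingConfig(min_alt_reads=1, min_alt_freq=0.0, min_depth=1)
    return _rna_candidates(rna, relaxed)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def editing_intensity(
    sites: list[EditingSite],
    mapped_read_totals: dict[str, int],
    design: StageDesign,
) -> pd.Series:
    """Events per million mapped reads, per stage (mean over replicates)."""
    out = {}
    for stage in design.stages:
        vals = []
        for rep in design.replicates[stage]:
            total = mapped_read_totals.get(rep, 0)
            if total <= 0:
                raise FdrmError(f"zero mapped reads for sample {rep}")
            n = sum(1 for s in sites if rep in s.support and stage in s.stages_present)
            vals.append(n / (total / 1e6))
        out[stage] = sum(vals) / len(vals)
    return pd.Series(out, name="events_per_million")


def stage_specificity(
    sites: list[EditingSite], design: StageDesign
) -> tuple[pd.DataFrame, pd.Series, dict[frozenset, int]]:
    """Presence matrix, per-stage stage-specific counts, and sharing table."""
    presence = pd.DataFrame(
        [[stage in s.stages_present for stage in design.stages] for s in sites],
        columns=design.stages,
        index=[f"{s.contig}:{s.pos0}:{s.alt_plus}" for s in sites],
    )
    specific = pd.Series(
        {
            stage: sum(1 for s in sites if s.stages_present == {stage})
            for stage in design.stages
        },
        name="stage_specific_sites",
    )
    sharing: dict[frozenset, int] = {}
    for s in sites:
        key = frozenset(s.stages_present)
        sharing[key] = sharing.get(key, 0) + 1
    return presence, specific, sharing


def type_histogram(sites: list[EditingSite]) -> pd.Series:
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.ed_type] = counts.get(s.ed_type, 0) + 1
    return pd.Series(counts, name="sites").sort_values(ascending=False)
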