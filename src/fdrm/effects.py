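"""Genic location, coding-consequence prediction, and term enrichment.

Coding effects use the standard nuclear genetic code (translation table 1).
For a stop-gaining edit at codon index c of an L-residue protein, the
residues c..L are all lost: residues_lost = L - c + 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fdrm.core_io.config import EnrichmentConfig
from fdrm.core_io.genome import GenomeRef
from fdrm.core_io.models import GeneModel, Interval
from fdrm.editing import EditingSite
from fdrm.errors import FdrmError, ModelError
from fdrm.splicing import ASEvent

FEATURES = ("CDS", "UTR5", "UTR3", "intron", "intergenic")

EFFECTS = ("synonymous", "missense", "stop_gained", "stop_lost", "noncoding")


@dataclass
class FeatureAnnotation:
    site_id: str
    feature: str
    gene_id: str | None = None
    codon_index: int | None = None     # 1-based
    codon_position: int | None = None  # 1, 2 or 3, transcript orientation
    effect: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    residues_lost: int | None = None


@dataclass
class IsoformEffect:
    event_id: str
    consequence: str  # in_frame_insertion | in_frame_deletion | frameshift |
                      # premature_stop | utr_only | noncoding
    aa_delta: int | None = None


# ---------------------------------------------------------------------------
# site location
# ---------------------------------------------------------------------------


def _locate_in_gene(pos0: int, gene: GeneModel) -> str:
    """Feature with precedence CDS > UTR > intron within one gene."""
    if gene.in_intervals(pos0, gene.cds):
        return "CDS"
    if gene.in_intervals(pos0, gene.utr5):
        return "UTR5"
    if gene.in_intervals(pos0, gene.utr3):
        return "UTR3"
    if gene.in_intervals(pos0, gene.exons):
        # exonic but not CDS/annotated UTR: side relative to CDS decides
        if gene.cds:
            before = pos0 < gene.cds[0][0]
            return ("UTR5" if before else "UTR3") if gene.strand == "+" else \
                   ("UTR3" if before else "UTR5")
        return "UTR5"
    return "intron"


def locate_site(
    site: EditingSite, gene_models: list[GeneModel], genome: GenomeRef | None = None
) -> list[FeatureAnnotation]:
    """All per-gene annotations for a site; the first entry is primary.

    Precedence within a gene is CDS > UTR > intron; across overlapping
    genes the CDS-bearing annotation sorts first.
    """
    if genome is not None and site.pos0 >= genome.length(site.contig):
        raise FdrmError(f"site {site.contig}:{site.pos0} beyond contig end")
    site_id = f"{site.contig}:{site.pos0}:{site.alt_plus}"
    hits = [m for m in gene_models if m.contig == site.contig and m.contains(site.pos0)]
    if not hits:
        return [FeatureAnnotation(site_id=site_id, feature="intergenic")]
    anns = []
    for gene in hits:
        feature = _locate_in_gene(site.pos0, gene)
        ann = FeatureAnnotation(site_id=site_id, feature=feature, gene_id=gene.gene_id)
        if feature == "CDS":
            off = gene.cds_offset(site.pos0)
            ann.codon_index = off // 3 + 1
            ann.codon_position = off % 3 + 1
        anns.append(ann)
    anns.sort(key=lambda a: FEATURES.index(a.feature))
    return anns


# ---------------------------------------------------------------------------
# coding effect of an edit
# ---------------------------------------------------------------------------


def _translate(cds: str) -> str:
    """Protein through the first stop (stop excluded)."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate(table=1))
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


def predict_coding_effect(
    site: EditingSite, gene: GeneModel, genome: GenomeRef
) -> FeatureAnnotation:
    """Substitute the edited base in its codon and classify the change."""
    cds_seq = gene.cds_sequence(genome)
    if len(cds_seq) % 3 != 0:
        raise ModelError(f"{gene.gene_id}: CDS length not divisible by 3")
    off = gene.cds_offset(site.pos0)
    codon_index = off // 3 + 1
    codon_pos = off % 3 + 1
    codon = cds_seq[(codon_index - 1) * 3: codon_index * 3]
    if len(codon) != 3:
        raise ModelError(f"{gene.gene_id}: edit in incomplete codon")
    if codon[codon_pos - 1] != site.ref_sense:
        raise FdrmError(
            f"{gene.gene_id}: codon base {codon[codon_pos - 1]} != site ref {site.ref_sense}")
    new_codon = codon[: codon_pos - 1] + site.alt_sense + codon[codon_pos:]
    table = standard_dna_table
    aa_ref = "*" if codon in table.stop_codons else table.forward_table[codon]
    aa_alt = "*" if new_codon in table.stop_codons else table.forward_table[new_codon]
    ann = FeatureAnnotation(
        site_id=f"{site.contig}:{site.pos0}:{site.alt_plus}",
        feature="CDS",
        gene_id=gene.gene_id,
        codon_index=codon_index,
        codon_position=codon_pos,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
    )
    protein_length = len(cds_seq) // 3 - 1  # residues, stop codon excluded
    if aa_ref == aa_alt:
        ann.effect = "synonymous"
    elif aa_alt == "*":
        ann.effect = "stop_gained"
        ann.residues_lost = protein_length - codon_index + 1
    elif aa_ref == "*":
        ann.effect = "stop_lost"
    else:
        ann.effect = "missense"
    return ann


# ---------------------------------------------------------------------------
# isoform effect of a splicing event
# ---------------------------------------------------------------------------


def _merge_intron(exons: list[Interval], intron: Interval) -> list[Interval]:
    out = []
    for iv in exons:
        if out and out[-1][1] == intron[0] and iv[0] == intron[1]:
            out[-1] = (out[-1][0], iv[1])
        else:
            out.append(iv)
    return out


def isoform_exon_structures(
    event: ASEvent, gene: GeneModel
) -> tuple[list[Interval], list[Interval]]:
    """(inclusion exons, exclusion exons) for an event against its gene model."""
    exons = list(gene.exons)
    if event.as_type == "IR":
        return _merge_intron(exons, event.intron or event.region), exons
    if event.as_type == "CE":
        return exons, [iv for iv in exons if iv != event.region]
    if event.as_type in {"A5SS", "A3SS"}:
        inc_j, exc_j = event.inc_junctions[0], event.exc_junctions[0]
        ann_set = set(gene.introns)
        ann_j = inc_j if inc_j in ann_set else exc_j
        idx = gene.introns.index(ann_j)

        def structure(junc: Junction_) -> list[Interval]:
            # splice the flanking exon edges to the junction's intron
            d, a = junc
            ex = list(exons)
            ex[idx] = (ex[idx][0], d)
            ex[idx + 1] = (a, ex[idx + 1][1])
            return ex

        return structure(inc_j), structure(exc_j)
    if event.as_type in {"AFE", "ALE"}:
        ann_j, novel_j = event.inc_junctions[0], event.exc_junctions[0]
        idx = gene.introns.index(ann_j)
        if ann_j[0] == novel_j[0]:  # shared donor: downstream terminus replaced
            alt = exons[: idx + 1] + [event.region]
        else:  # shared acceptor: upstream terminus replaced
            alt = [event.region] + exons[idx + 1:]
        return exons, alt
    if event.as_type == "MXE":
        x0, y1 = event.region
        middle = [iv for iv in exons if x0 <= iv[0] and iv[1] <= y1]
        if len(middle) != 2:
            raise ModelError(f"{event.event_id}: MXE region does not span two exons")
        inc = [iv for iv in exons if iv != middle[1]]
        exc = [iv for iv in exons if iv != middle[0]]
        return inc, exc
    raise FdrmError(f"isoform structures undefined for type {event.as_type}")


_STRUCTURED_TYPES = {"IR", "CE", "A5SS", "A3SS", "MXE", "AFE", "ALE"}


Junction_ = tuple[int, int]


def predict_isoform_effect(
    event: ASEvent, gene: GeneModel, genome: GenomeRef
) -> IsoformEffect:
    """Translate both isoforms and classify the consequence on the protein."""
    if not gene.cds or event.as_type not in _STRUCTURED_TYPES:
        return IsoformEffect(event.event_id, "noncoding")
    inc_exons, exc_exons = isoform_exon_structures(event, gene)
    # reference = the annotated structure; alternative = the novel isoform
    if exc_exons == gene.exons:
        ref_exons, alt_exons = exc_exons, inc_exons
    else:
        ref_exons, alt_exons = inc_exons, exc_exons
    ref_prot = _protein_from_structure(gene, genome, ref_exons)
    alt_prot = _protein_from_structure(gene, genome, alt_exons)
    if ref_prot is None or alt_prot is None:
        return IsoformEffect(event.event_id, "noncoding")
    if alt_prot == ref_prot:
        return IsoformEffect(event.event_id, "utr_only", aa_delta=0)
    delta_nt = sum(e - s for s, e in alt_exons) - sum(e - s for s, e in ref_exons)
    if delta_nt % 3 != 0:
        return IsoformEffect(event.event_id, "frameshift",
                             aa_delta=len(alt_prot) - len(ref_prot))
    expected = len(ref_prot) + delta_nt // 3
    if len(alt_prot) < expected:
        return IsoformEffect(event.event_id, "premature_stop",
                             aa_delta=len(alt_prot) - len(ref_prot))
    kind = "in_frame_insertion" if delta_nt > 0 else "in_frame_deletion"
    return IsoformEffect(event.event_id, kind, aa_delta=delta_nt // 3)


def _protein_from_structure(
    gene: GeneModel, genome: GenomeRef, exons: list[Interval]
) -> str | None:
    """Translate a spliced structure from the annotated start codon."""
    cds_start = gene.cds[0][0] if gene.strand == "+" else gene.cds[-1][1] - 1
    offset = 0
    found = False
    for s, e in (exons if gene.strand == "+" else reversed(exons)):
        lo, hi = (s, e)
        if lo <= cds_start < hi:
            offset += (cds_start - lo) if gene.strand == "+" else (hi - 1 - cds_start)
            found = True
            break
        offset += hi - lo
    if not found:
        return None
    transcript = gene.spliced_sequence(genome, exons)
    cds = transcript[offset:]
    if not cds.startswith("ATG"):
        return None
    return _translate(cds)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    term: str
    hits_k: int
    set_size_n: int
    term_size_K: int
    background_N: int
    pvalue: float
    qvalue: float = float("nan")


def enrich_terms(
    gene_set: set[str],
    term_map: pd.DataFrame,
    background: set[str],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment with BH correction.

    ``term_map`` is a two-column frame (gene, term). Terms passing
    p < pvalue_cutoff and q < qvalue_cutoff (both 0.2 by default) are
    returned, sorted by p.
    """
    cfg = config or EnrichmentConfig()
    if not background:
        raise FdrmError("empty background gene set")
    stray = gene_set - background
    if stray:
        raise FdrmError(f"gene set not contained in background: {sorted(stray)[:5]}")
    tm = term_map[term_map.iloc[:, 0].isin(background)]
    n_bg = len(background)
    n_set = len(gene_set)
    results = []
    for term, grp in tm.groupby(tm.columns[1]):
        term_genes = set(grp.iloc[:, 0])
        k = len(term_genes & gene_set)
        big_k = len(term_genes)
        pval = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_set))
        results.append(EnrichmentResult(term=str(term), hits_k=k, set_size_n=n_set,
                                        term_size_K=big_k, background_N=n_bg, pvalue=pval))
    if results:
        adj = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.qvalue = float(q)
    passing = [r for r in results
               if r.pvalue < cfg.pvalue_cutoff and r.qvalue < cfg.qvalue_cutoff]
    return sorted(passing, key=lambda r: r.pvalue)
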