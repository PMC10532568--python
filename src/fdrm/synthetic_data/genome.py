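"""Toy genome and gene-model generator.

Genes carry 2-6 exons, a complete CDS (ATG .. stop, length divisible by 3,
no internal stop), UTRs on both sides, and phylostratum/divergence labels.
Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import numpy as np

from fdrm.core_io.genome import GenomeRef, revcomp
from fdrm.core_io.models import GeneModel, Interval
from fdrm.errors import FdrmError

STOP_CODONS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) non-stop codons + stop; length 3*n_codons."""
    if n_codons < 2:
        raise FdrmError("CDS needs at least start and stop codons")
    body = [NON_STOP_CODONS[i] for i in rng.integers(0, len(NON_STOP_CODONS), n_codons - 2)]
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def random_intron(rng: np.random.Generator, length: int) -> str:
    if length < 4:
        raise FdrmError("intron too short for splice dinucleotides")
    return "GT" + _random_seq(rng, length - 4) + "AG"


def _map_transcript_interval(
    exon_local: list[Interval], t_start: int, t_end: int
) -> list[Interval]:
    """Map a transcript-coordinate interval onto local genomic exon pieces."""
    out = []
    offset = 0
    for s, e in exon_local:
        length = e - s
        lo = max(t_start - offset, 0)
        hi = min(t_end - offset, length)
        if lo < hi:
            out.append((s + lo, s + hi))
        offset += length
    return out


def assemble_gene(
    gene_id: str,
    contig: str,
    cds_seq: str,
    utr5_seq: str,
    utr3_seq: str,
    exon_lengths: list[int],
    intron_seqs: list[str],
    strand: str = "+",
    offset: int = 0,
    phylostratum: int | None = None,
    divergence_stratum: int | None = None,
) -> tuple[str, GeneModel]:
    """Build a gene's genomic sequence and model from explicit parts.

    ``exon_lengths`` partitions the transcript (UTR5+CDS+UTR3);
    ``intron_seqs`` has one entry per internal junction. Returns the
    plus-strand genomic sequence of the gene and the placed GeneModel.
    """
    transcript = utr5_seq + cds_seq + utr3_seq
    if sum(exon_lengths) != len(transcript):
        raise FdrmError(f"{gene_id}: exon lengths do not partition the transcript")
    if len(intron_seqs) != len(exon_lengths) - 1:
        raise FdrmError(f"{gene_id}: need one intron per internal junction")
    if len(cds_seq) % 3 != 0:
        raise FdrmError(f"{gene_id}: CDS length not divisible by 3")

    # local (sense) genomic layout
    exon_local: list[Interval] = []
    seq_parts: list[str] = []
    pos = 0
    t_off = 0
    for i, ex_len in enumerate(exon_lengths):
        exon_local.append((pos, pos + ex_len))
        seq_parts.append(transcript[t_off: t_off + ex_len])
        pos += ex_len
        t_off += ex_len
        if i < len(intron_seqs):
            seq_parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    gene_seq = "".join(seq_parts)

    u5 = len(utr5_seq)
    cds_local = _map_transcript_interval(exon_local, u5, u5 + len(cds_seq))
    utr5_local = _map_transcript_interval(exon_local, 0, u5)
    utr3_local = _map_transcript_interval(exon_local, u5 + len(cds_seq), len(transcript))

    if strand == "-":
        n = len(gene_seq)
        gene_seq = revcomp(gene_seq)
        flip = lambda iv: (n - iv[1], n - iv[0])
        exon_local = sorted(flip(iv) for iv in exon_local)
        cds_local = sorted(flip(iv) for iv in cds_local)
        utr5_local = sorted(flip(iv) for iv in utr5_local)
        utr3_local = sorted(flip(iv) for iv in utr3_local)

    shift = lambda ivs: [(s + offset, e + offset) for s, e in ivs]
    model = GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=shift(exon_local),
        cds=shift(cds_local),
        utr5=shift(utr5_local),
        utr3=shift(utr3_local),
        phylostratum=phylostratum,
        divergence_stratum=divergence_stratum,
    )
    return gene_seq, model


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random partition of `total` into `parts` pieces each >= minimum."""
    if total < parts * minimum:
        raise FdrmError("infeasible exon packing")
    slack = total - parts * minimum
    cuts = np.sort(rng.integers(0, slack + 1, parts - 1))
    pieces = np.diff(np.concatenate([[0], cuts, [slack]]))
    return [minimum + int(p) for p in pieces]


def simulate_genome(
    n_genes: int,
    exons_per_gene_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    contig_name: str = "scaffold_1",
    phylostratum_weights: list[float] | None = None,
    min_exon_len: int = 30,
    codon_range: tuple[int, int] = (60, 180),
    intron_range: tuple[int, int] = (60, 90),
) -> tuple[GenomeRef, list[GeneModel]]:
    if n_genes < 1:
        raise FdrmError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if phylostratum_weights is None:
        # old strata are more populated, loosely mirroring real phylostratigraphy
        w = np.array([12, 10, 8, 7, 6, 5, 4, 4, 3, 3, 2, 2], dtype=float)
        phylostratum_weights = list(w / w.sum())
    lo_ex, hi_ex = exons_per_gene_range
    parts: list[str] = []
    models: list[GeneModel] = []
    pos = 0
    for gi in range(1, n_genes + 1):
        gap = _random_seq(rng, int(rng.integers(100, 201)))
        parts.append(gap)
        pos += len(gap)
        n_ex = int(rng.integers(lo_ex, hi_ex + 1))
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        cds = random_cds(rng, n_codons)
        utr5 = _random_seq(rng, int(rng.integers(30, 61)))
        utr3 = _random_seq(rng, int(rng.integers(30, 61)))
        exon_lengths = _split_lengths(rng, len(utr5) + len(cds) + len(utr3),
                                      n_ex, min_exon_len)
        introns = [random_intron(rng, int(rng.integers(*intron_range)))
                   for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_seq, model = assemble_gene(
            gene_id=f"G{gi:05d}",
            contig=contig_name,
            cds_seq=cds,
            utr5_seq=utr5,
            utr3_seq=utr3,
            exon_lengths=exon_lengths,
            intron_seqs=introns,
            strand=strand,
            offset=pos,
            phylostratum=int(rng.choice(np.arange(1, 13), p=phylostratum_weights)),
            divergence_stratum=int(rng.integers(1, 11)),
        )
        parts.append(gene_seq)
        pos += len(gene_seq)
        models.append(model)
    parts.append(_random_seq(rng, int(rng.integers(100, 201))))
    genome = GenomeRef({contig_name: "".join(parts)})
    return genome, models
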