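"""GFF3 reading/writing for gene models.

GFF3 is 1-based inclusive; conversion to the internal 0-based half-open
convention happens here and only here.
"""
from __future__ import annotations

import logging
from pathlib import Path

import gffutils

from fdrm.core_io.models import GeneModel, Interval
from fdrm.errors import FormatError, ModelError

log = logging.getLogger(__name__)

_UTR5_TYPES = {"five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR"}


def _iv(feature) -> Interval:
    # GFF3 start/end are 1-based inclusive
    return (feature.start - 1, feature.end)


def _int_attr(feature, key: str) -> int | None:
    vals = feature.attributes.get(key)
    if not vals:
        return None
    return int(vals[0])


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into validated GeneModels.

    Only the first mRNA of each gene is used as the reference isoform;
    additional isoforms are ignored with a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            sort_attribute_values=False,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in {"+", "-"}:
            raise FormatError(f"{gene.id}: unknown strand {gene.strand!r}")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        if len(mrnas) > 1:
            log.warning("%s: %d mRNAs, using the first", gene.id, len(mrnas))
        exons = [_iv(f) for f in db.children(parent, featuretype="exon")]
        cds = [_iv(f) for f in db.children(parent, featuretype="CDS")]
        utr5, utr3 = [], []
        for f in db.children(parent):
            if f.featuretype in _UTR5_TYPES:
                utr5.append(_iv(f))
            elif f.featuretype in _UTR3_TYPES:
                utr3.append(_iv(f))
        if not exons:
            raise ModelError(f"{gene.id}: no exon features")
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                phylostratum=_int_attr(gene, "phylostratum"),
                divergence_stratum=_int_attr(gene, "divergence_stratum"),
            )
        )
    return models


def _frame(cds: list[Interval], strand: str) -> list[int]:
    """GFF3 phase column for each CDS interval (transcript order applied)."""
    ivs = cds if strand == "+" else list(reversed(cds))
    frames, acc = [], 0
    for s, e in ivs:
        frames.append((3 - acc % 3) % 3)
        acc += e - s
    return frames if strand == "+" else list(reversed(frames))


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    """Emit models as GFF3 (one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = [f"ID={m.gene_id}"]
            if m.phylostratum is not None:
                attrs.append(f"phylostratum={m.phylostratum}")
            if m.divergence_stratum is not None:
                attrs.append(f"divergence_stratum={m.divergence_stratum}")
            row = [m.contig, "fdrm", "gene", str(m.start + 1), str(m.end),
                   ".", m.strand, ".", ";".join(attrs)]
            fh.write("\t".join(row) + "\n")
            tid = f"{m.gene_id}.t1"
            fh.write("\t".join([m.contig, "fdrm", "mRNA", str(m.start + 1), str(m.end),
                                ".", m.strand, ".", f"ID={tid};Parent={m.gene_id}"]) + "\n")
            for s, e in m.exons:
                fh.write("\t".join([m.contig, "fdrm", "exon", str(s + 1), str(e),
                                    ".", m.strand, ".", f"Parent={tid}"]) + "\n")
            for (s, e), fr in zip(m.cds, _frame(m.cds, m.strand)):
                fh.write("\t".join([m.contig, "fdrm", "CDS", str(s + 1), str(e),
                                    ".", m.strand, str(fr), f"Parent={tid}"]) + "\n")
            for s, e in m.utr5:
                fh.write("\t".join([m.contig, "fdrm", "five_prime_UTR", str(s + 1), str(e),
                                    ".", m.strand, ".", f"Parent={tid}"]) + "\n")
            for s, e in m.utr3:
                fh.write("\t".join([m.contig, "fdrm", "three_prime_UTR", str(s + 1), str(e),
                                    ".", m.strand, ".", f"Parent={tid}"]) + "\n")
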