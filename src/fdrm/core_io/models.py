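"""Gene model: the coordinate frame for annotation.

All internal coordinates are 0-based half-open. GFF3 input/output is
converted at the boundary (1-based inclusive per the standard).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from fdrm.core_io.genome import GenomeRef, revcomp
from fdrm.errors import ModelError

Interval = tuple[int, int]


def _sorted_disjoint(ivs: list[Interval], label: str, gene_id: str) -> list[Interval]:
    ivs = sorted(ivs)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ModelError(f"{gene_id}: overlapping {label} intervals {(s1, e1)} {(s2, e2)}")
    for s, e in ivs:
        if e <= s:
            raise ModelError(f"{gene_id}: empty {label} interval {(s, e)}")
    return ivs


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    phylostratum: int | None = None
    divergence_stratum: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ModelError(f"{self.gene_id}: unknown strand {self.strand!r}")
        self.exons = _sorted_disjoint(self.exons, "exon", self.gene_id)
        self.cds = _sorted_disjoint(self.cds, "CDS", self.gene_id)
        self.utr5 = _sorted_disjoint(self.utr5, "UTR5", self.gene_id)
        self.utr3 = _sorted_disjoint(self.utr3, "UTR3", self.gene_id)
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ModelError(f"{self.gene_id}: CDS {(s, e)} not contained in any exon")

    # ---- geometry -------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def introns(self) -> list[Interval]:
        """(donor0, acceptor0) pairs: first intronic base, first base after the intron."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_intervals(self, pos0: int, ivs: list[Interval]) -> bool:
        return any(s <= pos0 < e for s, e in ivs)

    # ---- transcript-frame helpers --------------------------------------

    def cds_offset(self, pos0: int) -> int:
        """0-based offset of a genomic position within the spliced CDS (sense strand)."""
        off = 0
        plus_off = None
        for s, e in self.cds:
            if s <= pos0 < e:
                plus_off = off + (pos0 - s)
                break
            off += e - s
        if plus_off is None:
            raise ModelError(f"{self.gene_id}: position {pos0} not in CDS")
        if self.strand == "+":
            return plus_off
        return self.cds_length - 1 - plus_off

    def cds_sequence(self, genome: GenomeRef) -> str:
        """Spliced CDS nucleotide sequence in transcript orientation."""
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def spliced_sequence(self, genome: GenomeRef, exons: list[Interval] | None = None) -> str:
        """Spliced transcript sequence (sense strand) for the given exon set."""
        exons = self.exons if exons is None else sorted(exons)
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in exons)
        return revcomp(seq) if self.strand == "-" else seq

    def splice_boundaries(self) -> list[int]:
        """Genomic positions of intron edges: first and last intronic base of each intron."""
        out = []
        for d0, a0 in self.introns:
            out.extend((d0, a0 - 1))
        return out
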