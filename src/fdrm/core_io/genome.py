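"""Reference genome container and FASTA round-trip."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from fdrm.errors import FormatError

_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRef:
    """Ordered map of contig name -> uppercase nucleotide string."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"empty sequence for contig {name!r}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise FormatError(f"contig {name!r} has non-ACGTN characters: {sorted(bad)}")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, contig: str, start0: int, end0: int) -> str:
        """Sequence of the 0-based half-open interval [start0, end0)."""
        return self.contigs[contig][start0:end0]


def read_genome(path: str | Path) -> GenomeRef:
    """Parse a FASTA file into a GenomeRef, uppercasing all sequence."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty record {rec.id!r} in {path}")
        contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeRef(contigs)


def write_genome(genome: GenomeRef, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
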