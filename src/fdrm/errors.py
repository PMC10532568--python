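"""Exception hierarchy shared across the package."""


class FdrmError(Exception):
    """Base class for all package errors."""


class FormatError(FdrmError):
    """Malformed input file (FASTA/GFF3/TSV/SAM dialect violations)."""


class ModelError(FdrmError):
    """Gene model violates structural constraints (e.g. CDS outside exons)."""


class ConsistencyError(FdrmError):
    """Cross-file inconsistency (e.g. pileup ref base disagrees with genome)."""


class DesignError(FdrmError):
    """Stage/replicate design violated (unknown stage, missing replicates)."""
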