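import numpy as np
import pytest

from fdrm.core_io import GenomeRef, StageDesign
from fdrm.core_io.models import GeneModel
from fdrm.synthetic_data import simulate_genome


@pytest.fixture(scope="session")
def design() -> StageDesign:
    return StageDesign()


@pytest.fixture(scope="session")
def toy_genome_models():
    """Small deterministic genome with 40 genes."""
    return simulate_genome(40, seed=11)


@pytest.fixture
def plus_gene() -> GeneModel:
    """3-exon plus-strand gene: exons [100,200) [260,340) [400,500)."""
    return GeneModel(
        gene_id="gplus",
        contig="chr1",
        strand="+",
        exons=[(100, 200), (260, 340), (400, 500)],
        cds=[(130, 200), (260, 340), (400, 470)],
        utr5=[(100, 130)],
        utr3=[(470, 500)],
        phylostratum=3,
    )


def make_genome_for(gene: GeneModel, seq_len: int = 600, seed: int = 0) -> GenomeRef:
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, seq_len))
    return GenomeRef({gene.contig: seq})
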