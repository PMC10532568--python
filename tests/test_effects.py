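import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from fdrm.core_io import GenomeRef, StageDesign
from fdrm.core_io.models import GeneModel
from fdrm.editing import EditingSite
from fdrm.effects import (
    EnrichmentResult,
    enrich_terms,
    isoform_exon_structures,
    locate_site,
    predict_coding_effect,
    predict_isoform_effect,
)
from fdrm.errors import FdrmError
from fdrm.splicing import ASEvent
from fdrm.synthetic_data import NON_STOP_CODONS, assemble_gene, random_cds


def _site(contig, pos0, ref, alt, strand="+"):
    from fdrm.editing import classify_editing_type
    return EditingSite(contig=contig, pos0=pos0, ref_plus=ref, alt_plus=alt,
                       strand=strand,
                       ed_type=classify_editing_type(ref, alt, strand))


def _single_exon_gene(cds: str, gene_id="g1", contig="c1", utr=30, offset=50,
                      strand="+"):
    """One-exon gene embedded in a random background contig."""
    rng = np.random.default_rng(1)
    utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, utr))
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, utr))
    seq, model = assemble_gene(gene_id, contig, cds, utr5, utr3,
                               exon_lengths=[utr + len(cds) + utr],
                               intron_seqs=[], strand=strand, offset=offset)
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, offset))
    genome = GenomeRef({contig: pad + seq + pad})
    return genome, model


# ---------------------------------------------------------------------------
# locate_site
# ---------------------------------------------------------------------------


class TestLocateSite:
    def test_codon_arithmetic(self):
        # 0-based CDS offset 1730 -> codon 577, position 3
        assert 1730 // 3 + 1 == 577 and 1730 % 3 + 1 == 3  # arithmetic oracle
        cds = random_cds(np.random.default_rng(0), 600)
        genome, model = _single_exon_gene(cds)
        pos0 = model.cds[0][0] + 1730
        ref = genome.fetch("c1", pos0, pos0 + 1)
        site = _site("c1", pos0, ref, {"A": "G", "C": "T", "G": "A", "T": "C"}[ref])
        (ann,) = locate_site(site, [model])
        assert ann.feature == "CDS"
        assert ann.codon_index == 577 and ann.codon_position == 3

    def test_downstream_of_stop_is_utr3(self):
        cds = random_cds(np.random.default_rng(0), 50)
        genome, model = _single_exon_gene(cds)
        pos0 = model.cds[0][1] + 10  # 10 nt past the stop, inside the mRNA
        ref = genome.fetch("c1", pos0, pos0 + 1)
        site = _site("c1", pos0, ref, {"A": "G", "C": "T", "G": "A", "T": "C"}[ref])
        (ann,) = locate_site(site, [model])
        assert ann.feature == "UTR3"

    def test_between_genes_is_intergenic(self):
        cds = random_cds(np.random.default_rng(0), 50)
        genome, model = _single_exon_gene(cds)
        ref = genome.fetch("c1", 5, 6)
        site = _site("c1", 5, ref, {"A": "G", "C": "T", "G": "A", "T": "C"}[ref])
        (ann,) = locate_site(site, [model])
        assert ann.feature == "intergenic"

    def test_beyond_contig_rejected(self):
        cds = random_cds(np.random.default_rng(0), 50)
        genome, model = _single_exon_gene(cds)
        site = _site("c1", genome.length("c1") + 5, "A", "G")
        with pytest.raises(FdrmError):
            locate_site(site, [model], genome)

    def test_codon_fields_round_trip_offset(self):
        cds = random_cds(np.random.default_rng(3), 120)
        genome, model = _single_exon_gene(cds)
        rng = np.random.default_rng(4)
        for off in rng.integers(0, len(cds), 50):
            pos0 = model.cds[0][0] + int(off)
            ref = genome.fetch("c1", pos0, pos0 + 1)
            site = _site("c1", pos0, ref, {"A": "G", "C": "T", "G": "A", "T": "C"}[ref])
            (ann,) = locate_site(site, [model])
            recovered = (ann.codon_index - 1) * 3 + (ann.codon_position - 1)
            assert recovered == off


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------


def _gene_with_codon(codon: str, codon_index: int, n_codons: int, strand="+"):
    """CDS whose `codon_index`-th codon is `codon` (1-based); no internal stop."""
    rng = np.random.default_rng(7)
    body = [NON_STOP_CODONS[i] for i in rng.integers(0, 61, n_codons)]
    body[0] = "ATG"
    body[codon_index - 1] = codon
    cds = "".join(body) + "TAA"
    genome, model = _single_exon_gene(cds, strand=strand)
    return genome, model


def _edit_at(genome, model, codon_index, codon_pos, alt_sense):
    off = (codon_index - 1) * 3 + codon_pos - 1
    if model.strand == "+":
        pos0 = model.cds[0][0] + off
        alt_plus = alt_sense
    else:
        pos0 = model.cds[-1][1] - 1 - off
        alt_plus = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt_sense]
    ref_plus = genome.fetch(model.contig, pos0, pos0 + 1)
    return _site(model.contig, pos0, ref_plus, alt_plus, model.strand)


class TestCodingEffect:
    def test_stop_gained_at_codon_577(self):
        """UAC -> UAG at codon 577 of a 713-residue protein loses 137 residues."""
        genome, model = _gene_with_codon("TAC", 577, 713)
        site = _edit_at(genome, model, 577, 3, "G")
        ann = predict_coding_effect(site, model, genome)
        assert ann.effect == "stop_gained"
        assert (ann.aa_ref, ann.aa_alt) == ("Y", "*")
        assert ann.residues_lost == 137

    def test_synonymous_leucine(self):
        genome, model = _gene_with_codon("CTT", 10, 40)
        site = _edit_at(genome, model, 10, 3, "C")  # CTT -> CTC, both Leu
        ann = predict_coding_effect(site, model, genome)
        assert ann.effect == "synonymous"

    def test_stop_lost(self):
        genome, model = _gene_with_codon("TAC", 5, 40)  # stop is the final TAA
        n = model.cds_length // 3
        site = _edit_at(genome, model, n, 3, "C")  # TAA -> TAC (Tyr)
        ann = predict_coding_effect(site, model, genome)
        assert ann.effect == "stop_lost"
        assert ann.aa_alt == "Y"

    def test_minus_strand_equivalent(self):
        genome, model = _gene_with_codon("TAC", 20, 50, strand="-")
        site = _edit_at(genome, model, 20, 3, "G")
        ann = predict_coding_effect(site, model, genome)
        assert ann.effect == "stop_gained"
        assert ann.residues_lost == 50 - 20 + 1

    def test_residues_lost_conservation(self):
        """lost + surviving(before the new stop) == original protein length."""
        rng = np.random.default_rng(11)
        genome, model = _gene_with_codon("TGG", 15, 60)  # Trp: W -> stop via G>A
        for codon_index in (2, 15, 59):
            cds = model.cds_sequence(genome)
            codon = cds[(codon_index - 1) * 3: codon_index * 3]
            # find a single-base change turning this codon into a stop
            done = False
            for pos in range(3):
                for alt in "ACGT":
                    new = codon[:pos] + alt + codon[pos + 1:]
                    if new in {"TAA", "TAG", "TGA"} and new != codon:
                        site = _edit_at(genome, model, codon_index, pos + 1, alt)
                        ann = predict_coding_effect(site, model, genome)
                        assert ann.effect == "stop_gained"
                        surviving = codon_index - 1
                        assert ann.residues_lost + surviving == len(cds) // 3 - 1
                        done = True
                        break
                if done:
                    break

    def test_agrees_with_full_translation_oracle(self):
        """synonymous <=> identical translated proteins, 10^4 random edits."""
        rng = np.random.default_rng(13)
        n_checked = 0
        while n_checked < 10_000:
            cds = random_cds(rng, int(rng.integers(20, 120)))
            genome, model = _single_exon_gene(cds)
            cds_start = model.cds[0][0]
            for _ in range(40):
                off = int(rng.integers(3, len(cds) - 3))  # skip start/stop codons
                ref = cds[off]
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == ref:
                    continue
                site = _site("c1", cds_start + off, ref, alt)
                ann = predict_coding_effect(site, model, genome)
                edited = cds[:off] + alt + cds[off + 1:]
                prot_ref = str(Seq(cds).translate(table=1, to_stop=True))
                prot_alt = str(Seq(edited).translate(table=1, to_stop=True))
                assert (ann.effect == "synonymous") == (prot_ref == prot_alt), \
                    (cds[off - off % 3: off - off % 3 + 3], alt, ann.effect)
                n_checked += 1


# ---------------------------------------------------------------------------
# isoform effects
# ---------------------------------------------------------------------------


def _ir_gene(intron_seq: str, n_exons=5, codons=100):
    """Multi-exon coding gene whose 3rd-4th exon junction sits inside the CDS
    at a codon boundary, with `intron_seq` as the retained intron."""
    rng = np.random.default_rng(23)
    cds = random_cds(rng, codons)
    utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    total = len(utr5) + len(cds) + len(utr3)
    # exon 3 ends at a codon boundary inside the CDS
    boundary = len(utr5) + (codons // 2) * 3
    cuts = [40, 80, boundary, boundary + 60]
    exon_lengths = [cuts[0]] + [b - a for a, b in zip(cuts, cuts[1:])] + [total - cuts[-1]]
    introns = ["GT" + "".join("ACGT"[i] for i in rng.integers(0, 4, 60)) + "AG"
               for _ in range(n_exons - 2)]
    introns.insert(2, intron_seq)  # between exons 3 and 4
    seq, model = assemble_gene("gIR", "c1", cds, utr5, utr3, exon_lengths,
                               introns[: n_exons - 1], strand="+", offset=10)
    genome = GenomeRef({"c1": "A" * 10 + seq + "A" * 10})
    return genome, model


def _ir_event(model) -> ASEvent:
    intron = model.introns[2]
    return ASEvent(event_id="e", gene_id=model.gene_id, contig=model.contig,
                   strand=model.strand, as_type="IR", region=intron, intron=intron,
                   exc_junctions=[intron])


def in_frame_intron(n_codons: int, codon: str = None) -> str:
    rng = np.random.default_rng(29)
    if codon is not None:
        return codon * n_codons
    return "".join(NON_STOP_CODONS[i] for i in rng.integers(0, 61, n_codons))


class TestIsoformEffect:
    def test_54nt_retained_intron_adds_18_residues(self):
        genome, model = _ir_gene(in_frame_intron(18))
        eff = predict_isoform_effect(_ir_event(model), model, genome)
        assert eff.consequence == "in_frame_insertion"
        assert eff.aa_delta == 18

    def test_57nt_serine_rich_intron_adds_19(self):
        genome, model = _ir_gene(in_frame_intron(19, codon="AGC"))
        eff = predict_isoform_effect(_ir_event(model), model, genome)
        assert eff.consequence == "in_frame_insertion"
        assert eff.aa_delta == 19

    def test_50nt_intron_frameshift(self):
        genome, model = _ir_gene(in_frame_intron(18)[:50])
        eff = predict_isoform_effect(_ir_event(model), model, genome)
        assert eff.consequence == "frameshift"

    def test_stop_in_retained_intron_terminates_early(self):
        intron = in_frame_intron(18)
        intron = intron[:9] + "TGA" + intron[12:]
        genome, model = _ir_gene(intron)
        eff = predict_isoform_effect(_ir_event(model), model, genome)
        assert eff.consequence == "premature_stop"

    def test_utr_intron_retention_is_utr_only(self):
        # put the variable intron between exons 1 and 2, inside the 5' UTR
        rng = np.random.default_rng(31)
        cds = random_cds(rng, 60)
        utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        total = len(utr5) + len(cds) + len(utr3)
        seq, model = assemble_gene(
            "gU", "c1", cds, utr5, utr3, exon_lengths=[30, total - 30],
            intron_seqs=["GT" + "A" * 56 + "AG"], strand="+", offset=5)
        genome = GenomeRef({"c1": "A" * 5 + seq + "A" * 5})
        intron = model.introns[0]
        ev = ASEvent(event_id="e", gene_id="gU", contig="c1", strand="+",
                     as_type="IR", region=intron, intron=intron)
        eff = predict_isoform_effect(ev, model, genome)
        assert eff.consequence == "utr_only"

    def test_cassette_exon_skip_in_frame_deletion(self):
        genome, model = _ir_gene(in_frame_intron(18))
        # skipping exon 4 removes exon4 length nucleotides from the CDS
        exon4 = model.exons[3]
        ev = ASEvent(event_id="e", gene_id=model.gene_id, contig="c1", strand="+",
                     as_type="CE", region=exon4)
        eff = predict_isoform_effect(ev, model, genome)
        length = exon4[1] - exon4[0]
        if length % 3 == 0:
            assert eff.consequence in {"in_frame_deletion", "premature_stop"}
        else:
            assert eff.consequence == "frameshift"


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def hypergeom_oracle(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) by direct summation of the hypergeometric mass."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return min(total, 1.0)


class TestEnrichment:
    def _fixture(self, rng, n_genes=60, n_terms=20):
        genes = [f"g{i}" for i in range(n_genes)]
        rows = []
        for t in range(n_terms):
            members = rng.choice(genes, size=rng.integers(3, 15), replace=False)
            rows.extend({"gene": g, "term": f"T{t}"} for g in members)
        return genes, pd.DataFrame(rows)

    def test_pvalues_match_enumeration(self):
        rng = np.random.default_rng(17)
        genes, tm = self._fixture(rng)
        gene_set = set(rng.choice(genes, size=15, replace=False))
        from fdrm.core_io.config import EnrichmentConfig
        cfg = EnrichmentConfig(pvalue_cutoff=1.1, qvalue_cutoff=1.1)
        results = enrich_terms(gene_set, tm, set(genes), cfg)
        assert results
        for r in results:
            assert r.pvalue == pytest.approx(
                hypergeom_oracle(r.hits_k, r.background_N, r.term_size_K, r.set_size_n),
                rel=1e-9)
            assert r.hits_k <= min(r.set_size_n, r.term_size_K)

    def test_fully_enriched_term_survives(self):
        tm = pd.DataFrame({"gene": ["g1", "g2", "g3"], "term": ["T"] * 3})
        background = {f"g{i}" for i in range(100)}
        results = enrich_terms({"g1", "g2", "g3"}, tm, background)
        assert len(results) == 1 and results[0].pvalue < 1e-4

    def test_absent_term_filtered(self):
        tm = pd.DataFrame({"gene": ["g50", "g51", "g52"], "term": ["T"] * 3})
        background = {f"g{i}" for i in range(100)}
        assert enrich_terms({"g1", "g2"}, tm, background) == []

    def test_empty_background_rejected(self):
        tm = pd.DataFrame({"gene": [], "term": []})
        with pytest.raises(FdrmError):
            enrich_terms(set(), tm, set())
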