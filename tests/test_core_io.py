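import numpy as np
import pandas as pd
import pysam
import pytest

from fdrm.core_io import (
    GenomeRef,
    StageDesign,
    read_alignments_to_pileup,
    read_as_events,
    read_editing_vcf,
    read_gene_models,
    read_genome,
    read_junction_tsv,
    read_pileup_tsv,
    write_as_events,
    write_editing_vcf,
    write_gene_models,
    write_genome,
    write_junction_tsv,
    write_pileup_tsv,
)
from fdrm.core_io.bed import events_to_table
from fdrm.core_io.models import GeneModel
from fdrm.editing import EditingSite
from fdrm.errors import ConsistencyError, DesignError, FormatError, ModelError
from fdrm.splicing import ASEvent


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


class TestStageDesign:
    def test_default_layout(self, design):
        assert design.stages == ["BS", "BS12h", "BS24h", "Myc", "Oidia", "Scl",
                                 "Knot", "Pri", "YFB"]
        assert all(len(design.replicates[s]) == 3 for s in design.stages)
        assert len(design.samples) == 27

    def test_exact_process_definitions(self, design):
        assert design.processes == {
            "germination": ["BS", "BS12h", "BS24h"],
            "oidiation": ["Myc", "Oidia"],
            "sclerotia": ["Myc", "Scl"],
            "fruiting": ["Myc", "Knot", "Pri"],
            "sporulation": ["Pri", "YFB", "BS"],
        }

    def test_unknown_stage_rejected(self, design):
        with pytest.raises(DesignError):
            design.check_stage("nope")

    def test_stage_of(self, design):
        assert design.stage_of("Scl_2") == "Scl"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestGenome:
    def test_two_contig_parse(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c2\nNNAC\nGT\n")
        g = read_genome(p)
        assert list(g.contigs) == ["c1", "c2"]
        assert g.length("c1") == 4 and g.length("c2") == 6

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgtn\n")
        assert read_genome(p)["c1"] == "ACGTN"

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(FormatError):
            read_genome(p)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(FormatError):
            GenomeRef({"c1": "ACGX"})

    def test_round_trip(self, tmp_path):
        g = GenomeRef({"c1": "ACGTN" * 30, "c2": "TTTTGGGG"})
        write_genome(g, tmp_path / "g.fa")
        assert read_genome(tmp_path / "g.fa").contigs == g.contigs


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF = """##gff-version 3
chr1\tsrc\tgene\t101\t500\t.\t-\t.\tID=g1;phylostratum=4
chr1\tsrc\tmRNA\t101\t500\t.\t-\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t-\t.\tParent=g1.t1
chr1\tsrc\texon\t261\t340\t.\t-\t.\tParent=g1.t1
chr1\tsrc\texon\t401\t500\t.\t-\t.\tParent=g1.t1
chr1\tsrc\tCDS\t131\t200\t.\t-\t0\tParent=g1.t1
chr1\tsrc\tCDS\t261\t340\t.\t-\t.\tParent=g1.t1
chr1\tsrc\tCDS\t401\t470\t.\t-\t.\tParent=g1.t1
"""


class TestGff:
    def test_minus_strand_three_exons(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        (m,) = read_gene_models(p)
        assert m.strand == "-"
        assert m.exons == [(100, 200), (260, 340), (400, 500)]  # ascending
        assert m.phylostratum == 4

    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t101\t200\t.\t+\t.\tID=g\n"
            "chr1\ts\tmRNA\t101\t200\t.\t+\t.\tID=t;Parent=g\n"
            "chr1\ts\texon\t101\t200\t.\t+\t.\tParent=t\n"
        )
        (m,) = read_gene_models(p)
        assert m.exons == [(100, 200)]  # GFF3 (101, 200) -> internal [100, 200)

    def test_cds_outside_exon_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t101\t200\t.\t+\t.\tID=g\n"
            "chr1\ts\tmRNA\t101\t200\t.\t+\t.\tID=t;Parent=g\n"
            "chr1\ts\texon\t101\t150\t.\t+\t.\tParent=t\n"
            "chr1\ts\tCDS\t140\t190\t.\t+\t0\tParent=t\n"
        )
        with pytest.raises(ModelError):
            read_gene_models(p)

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t101\t200\t.\t.\t.\tID=g\n"
            "chr1\ts\tmRNA\t101\t200\t.\t.\t.\tID=t;Parent=g\n"
            "chr1\ts\texon\t101\t200\t.\t.\t.\tParent=t\n"
        )
        with pytest.raises(FormatError):
            read_gene_models(p)

    def test_write_read_involution(self, tmp_path, toy_genome_models):
        _, models = toy_genome_models
        p = tmp_path / "models.gff3"
        write_gene_models(models, p)
        back = read_gene_models(p)
        assert len(back) == len(models)
        for a, b in zip(sorted(models, key=lambda m: m.gene_id), back):
            assert (a.gene_id, a.strand, a.exons, a.cds, a.utr5, a.utr3,
                    a.phylostratum) == (b.gene_id, b.strand, b.exons, b.cds,
                                        b.utr5, b.utr3, b.phylostratum)


# ---------------------------------------------------------------------------
# SAM/BAM pileup
# ---------------------------------------------------------------------------


def _write_bam(tmp_path, reads):
    """reads: list of (name, flag, pos0, mapq, seq, quals)."""
    sam = tmp_path / "t.sam"
    lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:1000"]
    for name, flag, pos0, mapq, seq, quals in reads:
        qual = "".join(chr(q + 33) for q in quals)
        lines.append(
            f"{name}\t{flag}\tchr1\t{pos0 + 1}\t{mapq}\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}"
        )
    sam.write_text("\n".join(lines) + "\n")
    bam = tmp_path / "t.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


class TestBamPileup:
    def test_clean_column(self, tmp_path):
        reads = [(f"r{i}", 0, 50, 60, "A", [30]) for i in range(10)]
        bam = _write_bam(tmp_path, reads)
        cols = list(read_alignments_to_pileup(bam, "s1", region=("chr1", 50, 51)))
        assert len(cols) == 1
        assert cols[0].counts["A"] == 10 and cols[0].depth == 10

    def test_low_base_quality_excluded(self, tmp_path):
        reads = [("ok", 0, 50, 60, "T", [30]), ("lowq", 0, 50, 60, "T", [20])]
        bam = _write_bam(tmp_path, reads)
        (col,) = read_alignments_to_pileup(bam, "s1", region=("chr1", 50, 51),
                                           min_base_q=25)
        assert col.counts["T"] == 1

    def test_mixed_tallies(self, tmp_path):
        reads = [(f"t{i}", 0, 50, 60, "T", [30]) for i in range(9)]
        reads += [(f"c{i}", 0, 50, 60, "C", [30]) for i in range(3)]
        bam = _write_bam(tmp_path, reads)
        (col,) = read_alignments_to_pileup(bam, "s1", region=("chr1", 50, 51))
        assert col.counts["T"] == 9 and col.counts["C"] == 3 and col.depth == 12

    def test_multihit_duplicate_lowmapq_excluded(self, tmp_path):
        reads = [
            ("keep", 0, 50, 60, "G", [30]),
            ("lowmapq", 0, 50, 10, "G", [30]),
            ("secondary", 256, 50, 60, "G", [30]),
            ("dup", 1024, 50, 60, "G", [30]),
        ]
        bam = _write_bam(tmp_path, reads)
        (col,) = read_alignments_to_pileup(bam, "s1", region=("chr1", 50, 51),
                                           min_map_q=25)
        assert col.counts["G"] == 1

    def test_unindexed_rejected(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n")
        with pytest.raises(FormatError):
            list(read_alignments_to_pileup(sam, "s1"))


# ---------------------------------------------------------------------------
# pileup / junction TSV
# ---------------------------------------------------------------------------


class TestTsvDialects:
    def test_pileup_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"contig": ["c1", "c1"], "pos0": [5, 9], "ref": ["A", "T"],
             "sample": ["s1", "s1"], "A": [10, 0], "C": [0, 2], "G": [0, 0],
             "T": [0, 28], "N": [0, 0]}
        )
        write_pileup_tsv(df, tmp_path / "p.tsv")
        back = read_pileup_tsv(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(back.drop(columns="source"), df)

    def test_depth_equals_tally_sum(self, tmp_path):
        from fdrm.core_io.pileup import pileup_rows_to_columns
        df = pd.DataFrame(
            {"contig": ["c1"], "pos0": [5], "ref": ["A"], "sample": ["s1"],
             "A": [7], "C": [1], "G": [2], "T": [3], "N": [4]}
        )
        (col,) = pileup_rows_to_columns(df)
        assert col.depth == 13  # N not counted

    def test_junction_round_trip_and_validation(self, tmp_path):
        df = pd.DataFrame(
            {"contig": ["c1"], "donor0": [100], "acceptor0": [200],
             "sample": ["s1"], "reads": [12], "clean_overhang_bases": [6]}
        )
        write_junction_tsv(df, tmp_path / "j.tsv")
        pd.testing.assert_frame_equal(read_junction_tsv(tmp_path / "j.tsv"), df)
        bad = df.assign(donor0=[300])
        write_junction_tsv(bad, tmp_path / "b.tsv")
        with pytest.raises(FormatError):
            read_junction_tsv(tmp_path / "b.tsv")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _site(**kw) -> EditingSite:
    base = dict(
        contig="c1", pos0=99, ref_plus="T", alt_plus="C", strand="+",
        ed_type="U-to-C", levels={"Myc_1": 0.081}, support={"Myc_1": (3, 37)},
        stages_present={"Myc"},
    )
    base.update(kw)
    return EditingSite(**base)


class TestVcf:
    def test_pos_is_one_based(self, tmp_path):
        write_editing_vcf([_site()], tmp_path / "e.vcf", ["Myc_1"])
        row = [l for l in (tmp_path / "e.vcf").read_text().splitlines()
               if not l.startswith("#")][0]
        assert row.split("\t")[1] == "100"  # internal 99 -> POS 100

    def test_level_printed_three_decimals(self, tmp_path):
        write_editing_vcf([_site()], tmp_path / "e.vcf", ["Myc_1"])
        assert "37:3:0.081" in (tmp_path / "e.vcf").read_text()

    def test_empty_site_list_header_only(self, tmp_path):
        write_editing_vcf([], tmp_path / "e.vcf", ["Myc_1"])
        lines = (tmp_path / "e.vcf").read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert lines[0] == "##fileformat=VCFv4.2"

    def test_ref_mismatch_rejected(self, tmp_path):
        genome = GenomeRef({"c1": "A" * 200})
        with pytest.raises(ConsistencyError):
            write_editing_vcf([_site()], tmp_path / "e.vcf", ["Myc_1"], genome)

    def test_round_trip(self, tmp_path, design):
        sites = [_site(), _site(pos0=150, ref_plus="G", alt_plus="A",
                                ed_type="G-to-A", gene_id="g1", feature="CDS")]
        write_editing_vcf(sites, tmp_path / "e.vcf", design.samples)
        back = read_editing_vcf(tmp_path / "e.vcf")
        assert len(back) == 2
        for a, b in zip(sites, back):
            assert (a.contig, a.pos0, a.ref_plus, a.alt_plus, a.ed_type,
                    a.stages_present, a.support) == \
                   (b.contig, b.pos0, b.ref_plus, b.alt_plus, b.ed_type,
                    b.stages_present, b.support)


# ---------------------------------------------------------------------------
# BED12 events table
# ---------------------------------------------------------------------------


class TestBed:
    def _event(self, strand="+"):
        ev = ASEvent(event_id="g1:CE:260-340", gene_id="g1", contig="chr1",
                     strand=strand, as_type="CE", region=(260, 340))
        ev.psi = {"BS": 0.5, "Myc": None}
        return ev

    def test_round_trip(self, tmp_path, design):
        ev = self._event()
        ev.psi = {s: 0.25 for s in design.stages}
        write_as_events([ev], tmp_path / "e.bed", design)
        back = read_as_events(tmp_path / "e.bed")
        assert back.loc[0, "chromStart"] == 260 and back.loc[0, "chromEnd"] == 340
        assert back.loc[0, "as_type"] == "CE"
        assert back.loc[0, "psi_BS"] == 0.25

    def test_minus_strand_keeps_ascending_coordinates(self, design):
        table = events_to_table([self._event(strand="-")], design)
        assert table.loc[0, "chromStart"] < table.loc[0, "chromEnd"]
        assert table.loc[0, "strand"] == "-"
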