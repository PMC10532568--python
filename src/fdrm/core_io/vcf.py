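"""VCF 4.2 writer/reader for called editing sites.

POS is 1-based per the VCF standard; REF/ALT are plus-strand bases.
INFO keys: EDTYPE (editing type, transcript sense), FEAT (genic feature),
EFFECT (coding effect), STAGES (comma list of stages carrying the site).
Per-sample FORMAT: DP (filtered depth), ED (edited reads), EL (editing level).
"""
from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

from fdrm.errors import ConsistencyError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from fdrm.core_io.genome import GenomeRef
    from fdrm.editing import EditingSite

_HEADER = """##fileformat=VCFv4.2
##source=fdrm
##INFO=<ID=EDTYPE,Number=1,Type=String,Description="Editing type on transcript sense strand">
##INFO=<ID=FEAT,Number=1,Type=String,Description="Genic feature (CDS/UTR5/UTR3/intron/intergenic)">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">
##INFO=<ID=STAGES,Number=.,Type=String,Description="Stages where the site is present">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand used for sense bases">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered depth">
##FORMAT=<ID=ED,Number=1,Type=Integer,Description="Reads supporting the edited base">
##FORMAT=<ID=EL,Number=1,Type=Float,Description="Editing level ED/DP">
"""


def write_editing_vcf(
    sites: list["EditingSite"],
    path: str | Path,
    samples: list[str],
    genome: "GenomeRef | None" = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" +
                 "FORMAT\t" + "\t".join(samples) + "\n")
        for site in sorted(sites, key=lambda s: (s.contig, s.pos0)):
            if genome is not None:
                ref = genome.fetch(site.contig, site.pos0, site.pos0 + 1)
                if ref != site.ref_plus:
                    raise ConsistencyError(
                        f"{site.contig}:{site.pos0}: site ref {site.ref_plus} != genome {ref}"
                    )
            info = [
                f"EDTYPE={site.ed_type}",
                f"FEAT={site.feature or '.'}",
                f"EFFECT={site.effect or '.'}",
                f"STAGES={','.join(sorted(site.stages_present)) or '.'}",
                f"GENE={site.gene_id or '.'}",
                f"STRAND={site.strand}",
            ]
            fields = []
            for s in samples:
                if s in site.support:
                    ed, dp = site.support[s]
                    level = site.levels.get(s)
                    el = f"{level:.3f}" if level is not None else "."
                    fields.append(f"{dp}:{ed}:{el}")
                else:
                    fields.append(".:.:.")
            row = [site.contig, str(site.pos0 + 1), ".", site.ref_plus, site.alt_plus,
                   ".", "PASS", ";".join(info), "DP:ED:EL"] + fields
            fh.write("\t".join(row) + "\n")


def read_editing_vcf(path: str | Path) -> list["EditingSite"]:
    """Parse a VCF written by :func:`write_editing_vcf` back into sites."""
    from fdrm.editing import EditingSite  # local import avoids a cycle

    sites: list[EditingSite] = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"malformed VCF row: {line!r}")
            contig, pos, _, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            info = dict(kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv)
            support, levels = {}, {}
            for sample, field in zip(samples, parts[9:]):
                dp, ed, el = field.split(":")
                if dp == ".":
                    continue
                support[sample] = (int(ed), int(dp))
                levels[sample] = None if el == "." else float(el)
            strand = info.get("STRAND", "+")
            stages = info.get("STAGES", ".")
            sites.append(
                EditingSite(
                    contig=contig,
                    pos0=pos - 1,
                    ref_plus=ref,
                    alt_plus=alt,
                    strand=strand,
                    ed_type=info.get("EDTYPE", "."),
                    support=support,
                    levels=levels,
                    stages_present=set() if stages == "." else set(stages.split(",")),
                    gene_id=None if info.get("GENE", ".") == "." else info["GENE"],
                    feature=None if info.get("FEAT", ".") == "." else info["FEAT"],
                    effect=None if info.get("EFFECT", ".") == "." else info["EFFECT"],
                )
            )
    return sites
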