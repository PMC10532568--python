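"""DNA/RNA pileup simulator with planted editing sites and negative controls.

DNA pileups are homozygous reference everywhere. RNA alt-base fractions are
drawn per replicate binomially around the true level. Editing types default
to a U-to-C-dominated mixture; levels follow a Beta with mean 0.081.
Four negative-control classes are plantable: (a) DNA-variant positions,
(b) splice-adjacent positions (within 4 nt), (c) single-replicate signals,
(d) sub-threshold coverage/frequency signals.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from fdrm.core_io.design import StageDesign
from fdrm.core_io.genome import GenomeRef
from fdrm.core_io.models import GeneModel
from fdrm.core_io.pileup import PILEUP_COLUMNS
from fdrm.errors import FdrmError
from fdrm.synthetic_data.manifest import TruthManifest

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# sense-strand (ref, alt) pairs and default mixture weights; U-to-C dominates
DEFAULT_TYPE_WEIGHTS: dict[str, float] = {
    "U-to-C": 0.55, "G-to-A": 0.09, "C-to-U": 0.08, "A-to-I(G)": 0.07,
    "A-to-C": 0.026, "A-to-U": 0.026, "C-to-A": 0.026, "C-to-G": 0.026,
    "G-to-C": 0.026, "G-to-U": 0.026, "U-to-A": 0.026, "U-to-G": 0.028,
}

_TYPE_TO_PAIR: dict[str, tuple[str, str]] = {}
for _r in "ACGU":
    for _a in "ACGU":
        if _r == _a:
            continue
        name = "A-to-I(G)" if (_r, _a) == ("A", "G") else f"{_r}-to-{_a}"
        _TYPE_TO_PAIR[name] = (_r.replace("U", "T"), _a.replace("U", "T"))

# default Beta(a, b) with mean a/(a+b) = 0.081
DEFAULT_LEVEL_DISTRIBUTION = (4.0, 45.383)


def _splice_distance_ok(
    pos0: int, boundaries: list[int], min_distance: int
) -> bool:
    return all(abs(pos0 - b) >= min_distance for b in boundaries)


def _site_positions(
    rng: np.random.Generator,
    genome: GenomeRef,
    gene_models: list[GeneModel],
    contig: str,
) -> list[tuple[int, GeneModel | None]]:
    """Shuffled candidate positions: exonic (with their gene) and intergenic."""
    seq_len = genome.length(contig)
    covered = np.zeros(seq_len, dtype=bool)
    out: list[tuple[int, GeneModel | None]] = []
    for m in gene_models:
        if m.contig != contig:
            continue
        covered[m.start:m.end] = True
        for s, e in m.exons:
            out.extend((p, m) for p in range(s, e))
    intergenic = np.flatnonzero(~covered)
    out.extend((int(p), None) for p in intergenic)
    rng.shuffle(out)
    return out


def simulate_editing(
    gene_models: list[GeneModel],
    genome: GenomeRef,
    design: StageDesign,
    n_sites: int = 60,
    type_weights: dict[str, float] | None = None,
    level_distribution: tuple[float, float] = DEFAULT_LEVEL_DISTRIBUTION,
    seed: int = 0,
    rna_depth: int = 100,
    dna_depth: int = 60,
    min_level: float | None = None,
    stage_count_probs: tuple[float, ...] = (0.75, 0.15, 0.10),
    n_negative_controls: tuple[int, int, int, int] = (0, 0, 0, 0),
    splice_margin: int = 5,
    mapped_reads_per_sample: int = 5_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Returns (DNA pileup, RNA pileup, manifest).

    Planted sites sit >= ``splice_margin`` nt from every splice boundary;
    class (b) negative controls deliberately violate that rule.
    """
    rng = np.random.default_rng(seed)
    weights = dict(type_weights or DEFAULT_TYPE_WEIGHTS)
    type_names = sorted(weights)
    w = np.array([weights[t] for t in type_names], dtype=float)
    w /= w.sum()
    a_par, b_par = level_distribution

    contig = gene_models[0].contig if gene_models else next(iter(genome.contigs))
    boundaries = [b for m in gene_models if m.contig == contig
                  for b in m.splice_boundaries()]
    candidates = _site_positions(rng, genome, gene_models, contig)
    used: set[int] = set()
    manifest = TruthManifest(seed=seed)
    dna_rows: list[dict] = []
    rna_rows: list[dict] = []

    def draw_level() -> float:
        for _ in range(1000):
            lev = float(rng.beta(a_par, b_par))
            if min_level is None or lev >= min_level:
                return lev
        raise FdrmError("cannot draw a level above min_level")

    def pick_position(ed_type: str, near_splice: bool = False) -> tuple[int, str, str, str]:
        """(pos0, ref_plus, alt_plus, strand) honouring the sense-type request."""
        ref_sense, alt_sense = _TYPE_TO_PAIR[ed_type]
        for pos0, gene in candidates:
            if pos0 in used:
                continue
            strand = gene.strand if gene is not None else "+"
            ref_plus = ref_sense if strand == "+" else _COMP[ref_sense]
            if genome.fetch(contig, pos0, pos0 + 1) != ref_plus:
                continue
            ok = _splice_distance_ok(pos0, boundaries, splice_margin)
            if near_splice:
                if ok or not _splice_distance_ok(pos0, boundaries, 1):
                    continue  # want distance in [1, margin-1]
            elif not ok:
                continue
            used.add(pos0)
            alt_plus = alt_sense if strand == "+" else _COMP[alt_sense]
            return pos0, ref_plus, alt_plus, strand
        raise FdrmError(f"no position available for type {ed_type}")

    def emit_dna(pos0: int, ref_plus: str, alt_plus: str | None = None,
                 alt_frac: float = 0.0) -> None:
        counts = {b: 0 for b in "ACGTN"}
        n_alt = int(round(dna_depth * alt_frac))
        counts[ref_plus] = dna_depth - n_alt
        if alt_plus and n_alt:
            counts[alt_plus] = n_alt
        dna_rows.append({"contig": contig, "pos0": pos0, "ref": ref_plus,
                         "sample": "DNA", **counts})

    def emit_rna(pos0: int, ref_plus: str, alt_plus: str, sample: str,
                 level: float, depth: int | None = None,
                 alt_override: int | None = None) -> tuple[int, int]:
        dp = int(depth if depth is not None else max(rng.poisson(rna_depth), 50))
        n_alt = int(rng.binomial(dp, level)) if alt_override is None else alt_override
        n_alt = min(n_alt, dp)
        counts = {b: 0 for b in "ACGTN"}
        counts[ref_plus] = dp - n_alt
        counts[alt_plus] = counts.get(alt_plus, 0) + n_alt
        rna_rows.append({"contig": contig, "pos0": pos0, "ref": ref_plus,
                         "sample": sample, **counts})
        return n_alt, dp

    def draw_stages() -> list[str]:
        k = int(rng.choice(np.arange(1, len(stage_count_probs) + 1),
                           p=np.array(stage_count_probs)))
        idx = rng.choice(len(design.stages), size=k, replace=False)
        return [design.stages[i] for i in sorted(idx)]

    # ---- true sites -----------------------------------------------------
    for _ in range(n_sites):
        ed_type = str(rng.choice(type_names, p=w))
        pos0, ref_plus, alt_plus, strand = pick_position(ed_type)
        level = draw_level()
        stages = draw_stages()
        emit_dna(pos0, ref_plus)
        for stage in design.stages:
            present = stage in stages
            for rep in design.replicates[stage]:
                emit_rna(pos0, ref_plus, alt_plus, rep, level if present else 0.0)
        manifest.planted_edits.append({
            "contig": contig, "pos0": pos0, "ref_plus": ref_plus,
            "alt_plus": alt_plus, "strand": strand, "ed_type": ed_type,
            "level": level, "stages": stages,
        })

    # ---- negative controls ---------------------------------------------
    classes = ("dna_variant", "splice_adjacent", "single_replicate", "sub_threshold")
    for cls, n_ctrl in zip(classes, n_negative_controls):
        for _ in range(n_ctrl):
            ed_type = str(rng.choice(type_names, p=w))
            pos0, ref_plus, alt_plus, strand = pick_position(
                ed_type, near_splice=(cls == "splice_adjacent"))
            level = max(draw_level(), 0.15)
            entry = {"contig": contig, "pos0": pos0, "ref_plus": ref_plus,
                     "alt_plus": alt_plus, "control_class": cls, "level": level}
            if cls == "dna_variant":
                emit_dna(pos0, ref_plus, alt_plus, alt_frac=0.35)
            else:
                emit_dna(pos0, ref_plus)
            if cls == "single_replicate":
                stage = design.stages[int(rng.integers(0, len(design.stages)))]
                lone = design.replicates[stage][0]
                for rep in design.samples:
                    emit_rna(pos0, ref_plus, alt_plus, rep,
                             level if rep == lone else 0.0)
                entry["stage"] = stage
            elif cls == "sub_threshold":
                variant = int(rng.integers(0, 3))
                for rep in design.samples:
                    if variant == 0:    # only 2 supporting reads
                        emit_rna(pos0, ref_plus, alt_plus, rep, 0.0,
                                 depth=100, alt_override=2)
                    elif variant == 1:  # frequency just under 3%
                        emit_rna(pos0, ref_plus, alt_plus, rep, 0.0,
                                 depth=140, alt_override=4)
                    else:               # coverage under 10
                        emit_rna(pos0, ref_plus, alt_plus, rep, 0.0,
                                 depth=8, alt_override=3)
                entry["variant"] = variant
            else:  # dna_variant / splice_adjacent carry a clear RNA signal
                for rep in design.samples:
                    emit_rna(pos0, ref_plus, alt_plus, rep, level)
            manifest.negative_controls.append(entry)

    manifest.mapped_read_totals.update(
        {rep: mapped_reads_per_sample for rep in design.samples})
    dna = pd.DataFrame(dna_rows, columns=PILEUP_COLUMNS)
    rna = pd.DataFrame(rna_rows, columns=PILEUP_COLUMNS)
    return dna, rna, manifest
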