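"""Count-matrix simulator with planted differentially expressed genes.

Counts are negative-binomial around gene- and stage-specific means;
dispersion 0 degenerates to Poisson. Six archetypal stage profiles serve
as mean templates for the profile-clustering recovery tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from fdrm.core_io.design import StageDesign
from fdrm.errors import FdrmError
from fdrm.synthetic_data.manifest import TruthManifest

# stage order: BS BS12h BS24h Myc Oidia Scl Knot Pri YFB
ARCHETYPES: dict[int, dict[str, float]] = {
    1: {"BS": .05, "BS12h": .05, "BS24h": .05, "Myc": .1, "Oidia": .1, "Scl": .1,
        "Knot": .3, "Pri": 1.0, "YFB": 1.0},           # fruiting-body high
    2: {"BS": .05, "BS12h": .1, "BS24h": .3, "Myc": 1.0, "Oidia": 1.0, "Scl": 1.0,
        "Knot": 1.0, "Pri": .2, "YFB": .1},            # mycelia-type high
    3: {"BS": .2, "BS12h": 1.0, "BS24h": 1.0, "Myc": .2, "Oidia": .1, "Scl": .1,
        "Knot": .1, "Pri": .05, "YFB": .05},           # early germination
    4: {"BS": .05, "BS12h": .05, "BS24h": .2, "Myc": 1.0, "Oidia": .8, "Scl": .8,
        "Knot": 1.0, "Pri": .05, "YFB": .05},          # mycelia, silent in fruiting
    5: {"BS": 1.0, "BS12h": .2, "BS24h": .1, "Myc": .05, "Oidia": .05, "Scl": .05,
        "Knot": .05, "Pri": .3, "YFB": 1.0},           # spore maturation / fresh spores
    6: {"BS": 1.0, "BS12h": 1.0, "BS24h": .8, "Myc": .1, "Oidia": .1, "Scl": .1,
        "Knot": .05, "Pri": .05, "YFB": .05},          # germination-wide
}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + phi mu^2; Poisson when dispersion == 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(
    gene_ids: list[str],
    design: StageDesign,
    n_deg: int = 20,
    dispersion: float = 0.05,
    seed: int = 0,
    lib_size: float = 1e6,
    planted_lfc: float = 4.0,
    deg_pairs: list[tuple[str, str]] | None = None,
    archetype_fraction: float = 0.3,
    base_cpm_log_mean: float = np.log(60.0),
    base_cpm_log_sigma: float = 0.8,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Counts (gene x sample) plus the truth of planted DEGs and archetypes."""
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    if n_deg > n_genes:
        raise FdrmError("more planted DEGs than genes")
    manifest = TruthManifest(seed=seed)
    base = np.exp(rng.normal(base_cpm_log_mean, base_cpm_log_sigma, n_genes))

    order = rng.permutation(n_genes)
    deg_idx = set(order[:n_deg])
    n_arch = int(archetype_fraction * n_genes)
    arch_idx = {i: 1 + int(k % 6) for k, i in enumerate(order[n_deg:n_deg + n_arch])}

    if deg_pairs is None:
        all_pairs = design.stage_pairs()
        deg_pairs = [all_pairs[int(rng.integers(0, len(all_pairs)))] for _ in range(n_deg)]
    deg_assign = dict(zip(sorted(deg_idx), deg_pairs))

    mean_cpm = np.tile(base[:, None], (1, len(design.stages)))
    stage_pos = {s: j for j, s in enumerate(design.stages)}
    for i, arch in arch_idx.items():
        prof = np.array([ARCHETYPES[arch][s] for s in design.stages])
        mean_cpm[i] = base[i] * prof / prof.max()
        manifest.archetypes[gene_ids[i]] = arch
    for i, (sa, sb) in deg_assign.items():
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * planted_lfc
        mean_cpm[i] = base[i]
        mean_cpm[i, stage_pos[sb]] = base[i] * 2.0 ** lfc
        manifest.planted_degs[gene_ids[i]] = {
            "stage_a": sa, "stage_b": sb, "log2fc": lfc,
        }

    counts = {}
    for stage in design.stages:
        for rep in design.replicates[stage]:
            mu = mean_cpm[:, stage_pos[stage]] / 1e6 * lib_size
            counts[rep] = _nb_draw(rng, mu, dispersion)
    df = pd.DataFrame(counts, index=gene_ids)[design.samples]
    manifest.mapped_read_totals.update(
        {rep: int(df[rep].sum()) for rep in design.samples})
    return df, manifest
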