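# fdrm

Analysis toolkit for developmental transcriptome modification in a
multi-stage fungal design: expression profiling, alternative-splicing (AS)
detection and differential splicing, RNA-editing (RE) calling from paired
DNA/RNA evidence, coding-effect prediction for edits and isoforms, and
phylotranscriptomic (TAI/TDI) profiling. A synthetic-data module generates
full datasets with planted ground truth (DEGs, AS events of eight types,
editing sites, negative controls) so the whole pipeline is testable offline.

The default experimental layout is nine developmental stages (BS, BS12h,
BS24h, Myc, Oidia, Scl, Knot, Pri, YFB) with three biological replicates
each, grouped into five processes (germination, oidiation, sclerotia
formation, fruiting, sporulation).

## Key thresholds (defaults, all configurable via YAML)

- Expression: expressed = CPM > 1 in ≥ 2/3 replicates of some stage; TMM
  normalization (30% M-trim, 5% A-trim, upper-quartile reference); DEG =
  |log2FC| > 2 and BH-adjusted p < 0.05 (NB exact test, common dispersion).
- Splicing: junction support ≥ 10 reads per stage, event coverage > 25,
  minor isoform ≥ 5 reads at > 5% abundance, junction overhang clean within
  6 bases; differential = |ΔPSI| > 0.1, Fisher p < 0.05, BH FDR < 0.05.
- Editing: per replicate ≥ 3 alt reads, ≥ 3% frequency, ≥ 10 coverage
  (base/mapping quality ≥ 25 when reading alignments); DNA must be deep
  (≥ 10) and fully reference; sites within 4 nt of a splice boundary are
  excluded; presence requires ≥ 2 replicates of a stage.
- Enrichment: hypergeometric upper tail, p < 0.2 and BH q < 0.2.

## CLI

Each stage reads/writes plain-text interchange files (FASTA, GFF3, TSV,
BED12-like, VCF 4.2) in a shared directory:

```sh
fdrm simulate   --out data --seed 1 --n-genes 120      # synthetic dataset + truth.json
fdrm expression --data data --out results              # TMM, CPM, RE, DE, clusters
fdrm splicing   --data data --out results              # AS events, PSI, differential
fdrm editing    --data data --out results              # editing.vcf + summaries
fdrm annotate   --data data --out results              # features, coding effects, enrichment
fdrm phylo      --data data --out results              # TAI/TDI, RV, PS-modification table
```

Thresholds can be overridden with `--config cfg.yaml`, e.g.

```yaml
editing:
  min_alt_reads: 5
splicing:
  delta_psi: 0.2
```

Besides the TSV evidence dialects, pileups can be built directly from
sorted+indexed BAM via `fdrm.core_io.read_alignments_to_pileup` (pysam),
with multi-hit/duplicate read exclusion and quality filters.

## Layout

- `src/fdrm/core_io/` — FASTA/GFF3/pileup/junction/VCF/BED readers & writers,
  stage design, configuration
- `src/fdrm/synthetic_data/` — genome/expression/splicing/editing simulators
  + truth manifest
- `src/fdrm/expression.py` — TMM, CPM filter, relative expression, NB exact
  test DE, Ward profile clustering
- `src/fdrm/splicing.py` — 8-type AS event classifier, filters, PSI,
  Fisher differential splicing, process specificity
- `src/fdrm/editing.py` — DNA/RNA comparison editing caller, 12 editing
  types, levels/intensity/stage specificity
- `src/fdrm/effects.py` — feature location, codon-level effect prediction,
  isoform translation effects, term enrichment
- `src/fdrm/phylo.py` — TAI/TDI, relative values, modification by
  phylostratum
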