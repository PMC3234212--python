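# nascentmetrics

Genome-wide tag-density metrics for studying how inflammatory genes are
poised and activated. Toll-like receptor 4 (TLR4) stimulation of macrophages
activates *immediate/early* (I/E) genes within an hour and *late* genes over
many hours. A recurring finding in this field is that I/E promoters carry
active histone marks and a promoter-proximally **paused RNA polymerase II**
before any stimulus, and that activation works largely by releasing Pol II
into productive elongation rather than by de novo recruitment.
`nascentmetrics` implements the quantitative procedures behind that style of
analysis, for GRO-Seq, ChIP-Seq, total RNA-Seq and CAGE tag libraries:

- **Tag processing** — BED6 tag libraries (one record per uniquely mapped
  read 5′ end) are depth-normalized to 10⁷ mapped tags (each tag carries
  weight `10⁷ / total_mapped`); ChIP tags are shifted by half the estimated
  fragment length toward the fragment center; promoter counts use a ±1 kb
  window around the TSS; TSS-anchored binned density profiles are
  gene-oriented; gene-body, exon and intron densities and RPKM are computed
  per gene.
- **Elongation efficiency** — per gene, the ratio of sense-strand GRO-Seq tag
  density in the gene body window `[+500, +2500)` to the density in the
  promoter-proximal window `[−25, +175)`. Values near 0 mean paused Pol II;
  an increase after stimulation means pause release.
- **Splicing efficiency**, two estimators from stranded total-RNA tags:
  `1 − (intron density / exon density)` (evaluable only when both raw
  densities exceed 1 read/kb), and a junction estimator,
  `1 − spanning/exonic`, comparing 32-bp read 3′ ends that extend across 5′
  splice junctions on the unspliced template (3′ ends in `[+7, +25]` of the
  first intronic base) with exonic 3′ ends in `[−25, −7]`.
- **Kinetic classification** — I/E: induced more than 3-fold at 1 h; late:
  induced less than 1.2-fold at 1 h but more than 4-fold at 12 h (strict
  inequalities). Induced-gene calling from paired GRO-Seq libraries uses
  depth-aware gene-body count tests (conditional binomial, Benjamini–Hochberg)
  with the filters fold change > 3, RPKM > 0.25 and FDR q < 0.10, plus
  genotype-overlap summaries and TSS-proximal (±500 bp) factor-binding calls.
- **Promoter sequence analysis** — CAGE-based TSS refinement (densest 100-bp
  window within ±1 kb, then the densest bp), promoter GC content over
  `[−500, +100)` with an optimal-discrimination GC cutoff between gene
  classes, positional TATA scanning restricted to motif starts in
  `[−35, −20]` (TATAWAWR consensus or any supplied PWM), and ZOOPS
  known-motif enrichment with exact hypergeometric p-values.
- **Synthetic data generator** — a small genome, non-overlapping gene models
  on both strands, and tag libraries whose statistical structure matches what
  the analysis assumes (paused-Pol II peak at +40 bp, bimodal histone
  profiles with a nadir near −50 bp, divergent GRO-Seq transcription,
  spliced/unspliced RNA mixtures, CAGE clusters offset from the annotated
  TSS, class-dependent promoter GC and TATA content), with every planted
  parameter recorded in a truth table so each estimator can be validated by
  parameter recovery.

## Worked example

Everything is driven by one YAML config. A fully synthetic run:

```yaml
# run.yaml
seed: 7
outdir: example_out
simulate:
  n_genes: 120
  genome_length: 1500000
  gene_length_range: [3000, 6000]
  library_sizes: {chip: 200000, gro: 300000, rna: 300000, cage: 24000}
```

```bash
nascentmetrics all --config run.yaml
```

prints (abridged):

```
INFO simulate: 120 genes in a 1500000 bp genome (seed 7)
INFO profile: chip_polii_basal mode at +37.5 bp
INFO metrics: basal aggregate junction splicing efficiency 0.921
INFO metrics: 120/120 promoters enriched over background
INFO classify: {'other': 46, 'late': 44, 'IE': 30}
INFO classify: 7 induced genes
INFO seqanalysis: GC cutoff 0.512 (discrimination 0.977)
INFO seqanalysis: refined 120/120 TSSs from CAGE
ok: manifest at example_out/run_manifest.json (31 output files)
```

Reading those lines: the shifted Pol II profile peaks in the 25-bp bin
containing +40 (the planted pause position); the pooled junction estimator
returns 0.92 for libraries whose planted splicing efficiencies average ≈0.92;
every promoter is called enriched over the uniform background (all simulated
genes carry promoter signal); the kinetic classifier recovers the planted
class mix; 7 genes clear the strict 3-fold induced-gene call (depth
normalization compresses global induction, so only the strongest I/E genes
pass — see `docs/methods.md`); and the GC cutoff splits the high-GC I/E from
the low-GC late promoters with near-perfect discrimination.

Outputs land in `example_out/`: TSV tables (`elongation.tsv`,
`elongation_paired.tsv`, `splicing.tsv`, `enrichment.tsv`,
`kinetic_classes.tsv`, `induced_calls.tsv`, `promoter_gc.tsv`,
`tata_hits.tsv`, `refined_tss.tsv`, `promoter_counts.tsv`, per-library
profiles), bedGraph tracks, the genome FASTA, BED12/GTF annotation, the truth
table, JSON summaries, and `run_manifest.json` with checksums — identical
config + seed reproduces identical checksums.

Real data enter through an `inputs:` block instead of `simulate:` (paths to a
genome FASTA, BED12/GTF gene models, and BED6 tag libraries); subcommands
(`simulate`, `profile`, `metrics`, `classify`, `seqanalysis`) run stages
individually.

The library API mirrors the CLI, e.g.:

```python
from nascentmetrics import read_tag_bed, read_bed12, elongation_efficiency
gro = read_tag_bed("gro_basal.bed")
genes = read_bed12("annotation.bed12")
rec = elongation_efficiency(gro, genes[0])   # .efficiency, .evaluable, ...
```

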