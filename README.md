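# methget

Correlate genome-wide DNA methylation (CG / CHG / CHH contexts, from WGBS
methylation calls) with gene expression, within one sample and between two
groups of samples.

The package consumes three inputs:

1. **Methylation calls** — CGmap format (8 tab-separated columns: chrom,
   nucleotide C/G, 1-based position, context, dinucleotide context, level,
   methylated reads, total reads; `.gz` accepted). Converters are provided
   for Bismark CX reports, BSMAP `methratio.py` output, methylpy allc files
   and METHimpute TSV exports.
2. **Gene expression** — two-column tab-delimited text (gene name, value such
   as RPKM/FPKM/CPM; unit-agnostic, header auto-detected).
3. **Gene annotation** — GTF with exon features (`gene_id` preferred,
   `gene_name` fallback). A second GTF of transposable elements may be
   supplied; TEs are treated as an additional annotation class.

From these it derives strand-aware per-gene regions (gene body, 2 kb
promoter, exon, intron, TE), averages methylation per gene × context ×
region (read-count-weighted by default, per-site mean optional, coverage
filter configurable), and runs:

- **correlation** — Pearson / Spearman of methylation vs expression with
  scatter and 2D-KDE plots;
- **ordinal** — methylation against expression rank with a moving-average
  trend curve and the unexpressed/expressed boundary;
- **grouping** — descriptive statistics of methylation across non-expressed
  genes plus expression quantiles (default 5);
- **metagene** — length-normalized ("region": 30 body windows, flanks of
  half the gene's length in 15 windows) or anchored ("site": ±2 kb around
  TSS/TES in 10 windows per side, down to single-base resolution) profiles
  per expression group;
- **comparison** — per-gene Δmethylation (A−B) vs log2 fold change
  (A/B, pseudocount 1), differential genes called as low-density outliers of
  a bivariate Gaussian mixture (default 1 component: chi-square(2) tail of
  the squared Mahalanobis distance; p < 1e−6), with quadrant counts;
- **heatmap** — joint hierarchical clustering of methylation (raw levels)
  and expression (log2, row-z-scored) for both groups.

A deterministic fixture generator (`methget synth`) emits CGmap + GTF +
expression files with planted methylation–expression correlations and a
designated differential subset, plus a truth table, so every analysis is
testable offline.

## CLI

All subcommands write their parameters to `manifest.json` in the output
directory and write numeric TSV tables before rendering figures.

```bash
# generate a two-group demo dataset
methget synth --seed 7 --n-genes 200 --two-group --n-diff-genes 20 -o fx/

# convert foreign methylation calls
methget convert --from bismark_cx -i sample.CX_report.txt -o sample.cgmap

# region BED files / cached methylation table
methget regions -g fx/annotation.gtf -o regions/
methget preprocess -m fx/groupB_rep1.cgmap -g fx/annotation.gtf \
    --min-coverage 4 -o meth.tsv

# single-methylome analyses (either --table meth.tsv or -m/-g inputs)
methget correlation --table meth.tsv -e fx/groupB_rep1.expression.tsv \
    --context CG --region promoter -o corr/
methget ordinal    --table meth.tsv -e fx/groupB_rep1.expression.tsv -o ord/
methget grouping   --table meth.tsv -e fx/groupB_rep1.expression.tsv -o grp/
methget metagene -m fx/groupB_rep1.cgmap -g fx/annotation.gtf \
    -e fx/groupB_rep1.expression.tsv --mode region -o mg/

# two-group analyses (comma-separate replicate files)
methget comparison -A fx/groupA_rep1.cgmap -B fx/groupB_rep1.cgmap \
    -eA fx/groupA_rep1.expression.tsv -eB fx/groupB_rep1.expression.tsv \
    -g fx/annotation.gtf --context CG --region genebody --alpha 1e-6 \
    --seed 7 -o cmp/
methget heatmap -A fx/groupA_rep1.cgmap -B fx/groupB_rep1.cgmap \
    -eA fx/groupA_rep1.expression.tsv -eB fx/groupB_rep1.expression.tsv \
    -g fx/annotation.gtf -o hm/
```

## Notes on defaults

- Methylation levels are recomputed from read counts (the CGmap level column
  is rounded and only validated).
- `--min-coverage` (default 4) excludes cytosines with fewer total reads and
  changes every downstream number; set `--min-coverage 1` to keep all sites.
- The weighted estimator is Σ methylated reads / Σ total reads over a
  region's sites; `site_mean` averages per-site levels instead.
- Promoters are anchored at the oriented gene-body start and clipped at
  position 1; promoters of adjacent genes are not masked against neighboring
  gene bodies.
- Genes with expression exactly 0 form group 0 ("non-expressed"); quantile
  ties are broken by gene name for determinism.
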