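# poolshift

Pooled-DNA allele-frequency analysis for replicated factorial larval
experiments. The package takes pooled sequencing data for a
2 groups × 2 stages × 2 treatments × n-replicates design from raw reads (or
per-sample nucleotide-count tables) through to functional enrichment:

1. **counts** — FASTQ quality filtering (36-bp truncation, phred screen),
   SAM → per-position nucleotide-count conversion (≥30 reference-matching
   bases), count-table merging and I/O.
2. **filters** — the locus-retention cascade: per-cell depth window
   [50, 1000], biallelic screen, one SNP per 36-bp tag, ≥3 replicates
   present per design cell, baseline minor-allele frequency > 1%.
3. **popgen** — pool-based allele frequencies, nucleotide diversity with a
   depth correction D/(D−1)·2f(1−f), heterozygosity-based pairwise F_ST,
   percentile bootstrap CIs, folded-spectrum K-S comparison, replicate PCA.
4. **effects** — per-locus binomial GLM (logit link, sum-to-zero contrasts)
   with the full model `Stage + Trt + Stage:Trt`; type III likelihood-ratio
   p-values, Benjamini-Hochberg correction per term, and exclusive category
   classification (None / Stage / Trt / Stage+Trt / Stage*Trt), plus the
   between-group category cross-tabulation and interaction-sign summary.
   The GLM solver is a vectorized IRLS fitted across all loci at once and is
   validated against statsmodels in the test suite.
5. **bridge** — linkage-group assignment of SNPs through scaffolds shared
   with a marker map, and Manhattan-style tables with BH threshold lines.
6. **enrich** — ±5 kb gene windows around mapped loci and gene-score
   resampling over GO terms with a simplified multifunctionality diagnostic.
7. **synthdata** — a generator for the full factorial design with known
   per-locus effect categories (logit-scale shifts, optional replicate-pool
   drift), used for power/FDR evaluation and throughout the tests.

## Command line

```sh
# synthetic experiment: counts + ground truth
poolshift simulate --n-loci 2000 --seed 1 --out sim/

# full pipeline (filter -> popgen -> effects -> bridge -> enrich)
poolshift all --counts sim/counts.tsv --out run/ --seed 1 \
    --linkage-map map.tsv --gff genes.gff3 --go-map go.tsv

# individual stages
poolshift filter  --counts sim/counts.tsv --out run/
poolshift effects --counts sim/counts.tsv --out run/
poolshift report  --counts sim/counts.tsv --out run/
```

Options may also be given as a YAML config (`--config run.yaml`); CLI flags
override the config, and each run writes its resolved configuration, a run
log, per-stage TSV tables and a `summary.json` beside its outputs.

Input count tables are tab-delimited with one row per sample × locus:
`sample_id group stage treatment replicate locus_id scaffold position
countA countC countG countT`.

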