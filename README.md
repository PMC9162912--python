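# editkit

A tested, reusable pipeline for genome-wide A-to-I RNA editing analysis
from aligned RNA-seq reads: high-confidence site calling, editing-level
quantification, annotation (region / recoding / repeats / sequence
context), temporal co-editing pattern discovery, ADAR-expression
regression, and barcode-split pseudobulk single-cell quantification.
A fully seeded synthetic-study generator drives the pipeline end to end
with serialized ground truth.

## What it does

1. **Site calling** (`editkit.call_sites`) — pileup of mapped reads with
   per-base quality filtering (base quality ≥ 25, mapping quality ≥ 20),
   candidate selection (coverage ≥ 15, A→G mismatch rate ≥ 0.02, third
   allele ≤ 1%), known-SNP exclusion against a VCF, and a recurrence
   filter keeping sites that are candidates in strictly more than 50% of
   samples. Genomic T→C sites are called as minus-strand A-to-I events.
   Editing level is G/(G+A); the candidate mismatch rate and the overall
   sample-wide level (Σ edited / Σ covered) are kept distinct.
2. **Annotation** (`editkit.annotate`) — region assignment with a fixed
   precedence (CDS > 3'UTR > 5'UTR > ncRNA > intron > intergenic),
   strand-aware codon reconstruction and synonymous/non-synonymous
   classification (e.g. Q/R, Y/C, I/V), repeat-family overlap
   (innermost wins), a ±5 bp sequence-context base-frequency matrix, and
   an exact small-sample Wilcoxon rank-sum comparison of editing levels
   between B1, other-repeat, and non-repeat sites.
3. **Patterns** (`editkit.patterns`) — per-site mean imputation, k-means
   (k = 3 by default) over stage trajectories with clusters labelled
   high/medium/low by centroid grand mean, an SSE elbow curve with an
   advisory suggested k, OLS regression of overall editing on
   Adar1/Adar2 expression with Benjamini–Hochberg correction, and
   per-pattern composition tables.
4. **Pseudobulk** (`editkit.pseudobulk`) — cell-barcode splitting into
   cell-type read groups, per-type editing at the bulk high-confidence
   background sites (level = edited / mapped reads at site), per-type
   detected-site ratios, and an expression-matched gene-set module score
   per cell.
5. **Simulation** (`editkit.simulate`) — random reference with
   gene/repeat annotation, planted editing sites following three
   temporal trajectories, heterozygous SNP confounders, per-stage bulk
   SAMs, barcoded single-cell SAMs with per-type site ownership,
   expression tables, and a JSON ground truth. Byte-identical under the
   same seed.

## CLI

One executable with subcommands; all thresholds live in a YAML config
(defaults match the printed thresholds above) and can be overridden by
flags:

```sh
# generate a synthetic study into ./work
editkit simulate --out work

# call high-confidence sites from work/bulk/<stage>.sam
editkit call --out work            # accepts e.g. --min-coverage 20

# annotate, cluster patterns, regress on ADAR expression
editkit analyze --out work

# split barcoded reads and quantify per cell type
editkit pseudobulk --out work

# or everything at once, with a config file
editkit --config config.yaml run-all --out work
```

Outputs are TSV/JSON files under `work/results/` (`sites.tsv`,
`matrix.tsv`, `annotated.tsv`, `patterns.tsv`, `sse_curve.tsv`,
`regression.tsv`, `composition_*.tsv`, `context.tsv`,
`pseudobulk_evidence.tsv`, `site_ratio.tsv`, `module_scores.tsv`), plus
a manifest of input hashes and parameters per subcommand. Example
config:

```yaml
seed: 1
stages: [E14.5, E17.5, P0, P3, P7, P10, P14, P21]
filter:
  min_base_quality: 25
  min_coverage: 15
simulate:
  genome_length: 60000
  mean_coverage: 50.0
patterns:
  k: 3
  n_init: 10
pseudobulk:
  min_cov: 5
  min_edit: 2
```

## Layout

```
src/editkit/
  formats_io.py   SAM/FASTA/GTF/VCF/BED readers-writers, domain types
  simulate.py     synthetic corpus generator + ground truth
  call_sites.py   filter cascade, editing levels, site×stage matrix
  annotate.py     region / recoding / repeat / context / rank-sum
  patterns.py     k-means patterns, elbow, ADAR regression, composition
  pseudobulk.py   barcode split, per-type editing, module score
  cli.py          click CLI wiring the workflow
tests/            pytest suite incl. independent oracles (tests/oracles.py)
scripts/          acceptance.py
```

Coordinates are half-open 0-based internally; all user-facing positions
are 1-based.
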