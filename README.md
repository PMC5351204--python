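# methylshift

Case-control differential methylation analysis for RRBS-style cytosine
count data, built around a residual-bootstrap empirical null. The package
covers the full workflow:

- **synthetic_data** — RRBS-like case-control generator: bimodal CpG /
  low-mean CpH baselines, negative-binomial coverage, binomial methylated
  counts with logit-scale planted case effects, latent confounders,
  sample-level technical noise, planted DMRs, QC-failure injection
  (hypermethylated / non-bimodal / aberrant-coverage libraries), and
  Hardy–Weinberg genotypes with planted cis meQTLs. Every planted signal
  is indexed in a JSON-serializable `GroundTruth`.
- **io_formats** — cytosine-report and Bismark-coverage dialects, BED3+,
  CSV sample sheets, dosage TSVs, result writers. 1-based cytosine
  positions, 0-based half-open intervals, gzip-transparent.
- **preprocess** — coverage filtering (≥10×, per-sample 99.9th-percentile
  cap), median-coverage normalization, case/control site union, percent
  methylation, 25% least-variable site filter, 3-SD per-site outlier
  masking.
- **sva_qc** — iteratively reweighted surrogate-variable estimation
  protecting diagnosis, iterative 4-SD SV sample-outlier removal,
  cis meQTL scan and known-meQTL recovery, per-sample library-failure
  diagnostics.
- **site_diffmeth** — per-site weighted least squares (log10-coverage
  weights) batched across sites, residual-bootstrap null (shared
  resampling indices across sites), study-wide significance from the
  bootstrap min-p distribution.
- **global_shift** — hypermethylation-proportion test at p-value cutoffs
  0.05 / 5e-3 / 5e-4 against the bootstrap null.
- **dmr** — bump-hunting: maxgap-300 clustering, running-mean smoothing,
  data-driven cutoff, candidate regions, bootstrap FWER, Bonferroni
  0.05/24 significance.
- **enrichment** — Fisher-exact 2×2 enrichment of hypermethylated sites
  in genomic categories, beacon flanking, replicate-track intersection.
- **power_calc** — noncentral-t power for unequal group sizes and minimum
  detectable difference.
- **pipeline** — end-to-end orchestration from a YAML config with one
  seed, run logging, and TSV/BED outputs.

## CLI

```bash
# write a synthetic dataset (cytosine reports + sample sheet + ground truth)
methylshift simulate --out-dir data/ --n-cases 29 --n-controls 34 \
    --n-cpg 2000 --n-cph 5000 --seed 1

# per-sample library diagnostics
methylshift qc --data-dir data/

# full analysis on a dataset directory
methylshift fit --data-dir data/ --out-dir results/ -B 200 --seed 1

# or from a YAML config (see methylshift.pipeline.PipelineConfig)
methylshift run-all --config config.yaml

# power / minimum detectable difference
methylshift power --n1 34 --n2 29 --power 0.8 --sd 5.0
```

`fit`, `global-test`, `dmr`, and `enrich` run the same workflow and print
different result tables; outputs land in `--out-dir` as TSV/BED plus a
JSON run log.

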