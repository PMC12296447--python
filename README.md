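# telocus

Locus-specific transposable-element (TE) quantification for droplet-based
single-cell RNA-seq. Reads from TE-derived transcripts map ambiguously across
near-identical genomic copies; `telocus` resolves them to individual loci and
reports corrected per-cell UMI count matrices.

The pipeline has four stages:

1. **Ingest** — barcoded alignments (SAM/BAM with `CB`/`UB`/`AS`/`NH` and
   optional `GX` tags) are filtered to a cell whitelist and intersected with a
   locus-level TE annotation (GTF) into a sparse fragment × feature weight
   matrix. Alignments must cover a feature by a configurable overlap fraction
   (default 20%); sub-threshold or off-annotation alignments load into a
   dedicated no-feature column. Weights are `exp((AS − AS_best)/scale)`.
2. **Multimapper-aware UMI deduplication** — fragments sharing a cell
   barcode + UMI are binned; within a bin, a graph connects fragments whose
   candidate locus sets intersect (directly or transitively). Each connected
   component is one molecule; the most informative fragment is retained.
3. **Mixture model** — a pooled Bayesian mixture model is fitted by EM,
   estimating per-pool feature abundances (π) and reassignment proportions
   (θ) with Dirichlet-pseudocount priors (defaults π=0, θ=200000; up to 500
   iterations, parameter-change tolerance 1e-7). Pooling modes: `individual`
   (one model per cell), `pseudobulk` (one model for the sample), `celltype`
   (one model per provided label). Fit reports include lnL, BIC and AIC for
   pooling-mode selection.
4. **Reassignment & counting** — each fragment is assigned by the
   `best_exclude` rule (highest-posterior alignment; ties are excluded);
   counts are tallied per locus × cell, corrected for UMIs double-counted by
   a canonical-gene quantifier (via the `GX` tag), and written as a 10x-style
   `matrix.mtx` / `features.tsv` / `barcodes.tsv` triple. Subfamily
   aggregation and per-cell TE load are also provided.

A **bounds validator** computes feasibility intervals for true UMI counts
directly from the alignments — the upper bound from distinct TE-overlapping
(CB, UMI) pairs, the lower bound restricted to uniquely aligned reads — and
classifies any estimate as below/within/above, per sample, cell, or locus.

A **simulator** generates alignment-level fixtures (SAM text) with known
ground truth: per-pool Dirichlet abundances, PCR duplicates, subfamily-
structured multimapping decoys with score gaps, gene-overlap flags and
off-annotation reads.

## CLI

```sh
# simulate a fixture with ground truth
telocus simulate --n-cells 50 --n-loci 20 --seed 1 --out sim/

# run the pipeline
telocus run --alignments sim/reads.sam --gtf sim/annotation.gtf \
    --whitelist sim/whitelist.txt --pooling pseudobulk --out out/

# celltype pooling needs a barcode->label TSV
telocus run ... --pooling celltype --celltype-tsv sim/labels.tsv --out out/

# UMI-count feasibility bounds, classifying the pipeline's estimates
telocus bounds --alignments sim/reads.sam --gtf sim/annotation.gtf \
    --whitelist sim/whitelist.txt --scope cell --estimates-dir out/ --out bounds/

# roll locus counts up to subfamilies
telocus aggregate --matrix-dir out/ --gtf sim/annotation.gtf --out agg/
```

Key `run` options: `--min-overlap` (0.2), `--pi-prior` (0), `--theta-prior`
(200000), `--max-iter` (500), `--em-tol` (1e-7), `--reassign`
(`best_exclude` | `best_random` | `average`), `--seed`. Outputs include the
count matrix triple, `fit_report.tsv`, `dedup_report.tsv`,
`ingest_report.tsv`, `te_load.tsv` and a JSON run manifest; runs with the
same configuration are byte-identical.

## Notes

- `lnL_trace` records the observed-data log-likelihood (the EM objective,
  guaranteed non-decreasing); the complete-data log-likelihood is computed
  separately and used for BIC/AIC.
- Cells where one UMI labels two molecules with disjoint mapping locations
  are deliberately kept as two molecules by the deduplicator, and may exceed
  the distinct-UMI upper bound; this is expected and rare.
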