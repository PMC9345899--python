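# tsrdiv

Analysis pipeline for transcription-start diversity and promiscuous gene
expression: 5'-tag (CTSS) track building, power-law normalization to
tags-per-million, density-based clustering of TSSs into transcription start
regions (TSRs), cross-sample consensus merging, population-specific TSR
classification with enrichment statistics, leave-one-out tissue-specificity,
τ-based tissue-restricted-antigen scoring, and splicing-entropy analysis.
A seeded synthetic-data module generates inputs with the statistical
structure the pipeline assumes (power-law tag counts, planted group-specific
promoters, planted τ classes, Dirichlet isoform usage) together with ground
truth, so every stage is testable without external data.

## Command line

All functionality is exposed through the `tsrdiv` entry point:

```sh
# generate a synthetic dataset (CTSS tracks, GTF, gene sets, TPM matrices, truth)
tsrdiv simulate --config configs/synthetic_small.yaml --outdir sim/

# single stages
tsrdiv normalize --ctss sim/hi_1.ctss.tsv --out hi_1.norm.tsv
tsrdiv call-tsr  --ctss hi_1.norm.tsv --out hi_1.tsrs.bed
tsrdiv saturation --ctss sim/hi_1.ctss.tsv --proportions 0.1,0.5,1.0 --seed 1
tsrdiv tau --matrix sim/gene_tpm.tsv --out tau.tsv
tsrdiv entropy --matrix sim/transcript_tpm.tsv --map sim/transcript_map.tsv --out H.tsv

# end-to-end runs (YAML config listing inputs; manifest.json records checksums)
tsrdiv run-tsr  --config tsr.yaml  --outdir tsr_out/
tsrdiv run-expr --config expr.yaml --outdir expr_out/
```

A `run-tsr` config names the per-sample CTSS files, the sample/group design
TSV, a minimal GTF annotation, and optional gene-set lists and BED3
features; `run-expr` names the gene- and transcript-level TPM matrices and
the transcript→gene map (see `tests/test_pipeline.py` for worked examples).

## File formats

* **CTSS**: TSV `chrom  pos0  strand  count` (0-based; `#` comments;
  `--one-based` reader flag for 1-based dialects).
* **TSRs**: BED6, half-open intervals, score = min(1000, round(signal)).
* **Annotation**: minimal GTF with `gene`/`exon`/`CDS` features and
  `gene_id`/`transcript_id` attributes.
* **Matrices / design / truth tables**: TSV with headers; gene sets: one id
  per line.

## Method notes

* Clustering builds the full density hierarchy (each cluster is maximal
  under the score `signal − d·span` for densities `d ∈ [min_density,
  max_density)`); the test suite proves equivalence with an independent
  Ruzzo–Tompa maximal-scoring-segment oracle. Default filters: ≥ 2
  tags-per-million and ≤ 20 bp per TSR; consensus merges TSRs within 20 bp
  on the same strand.
* Normalization fits the log-log reverse-cumulative count distribution and
  maps counts rank-for-rank onto a reference power law (slope 1.25, total
  10⁶); refitting a normalized track recovers the reference slope and
  implied total.
* A TSR is population-specific when present in ≥ 2 samples of one group and
  none of the other; enrichment uses two-sided Fisher exact tests with
  Woolf CIs (Haldane correction on zero cells), paired t-tests over
  individuals, and exact Mann–Whitney U for small groups.
* τ = Σ(1 − xᵢ/max x)/(n − 1) on features with max TPM ≥ 1; features with
  τ ≥ 0.8 are tissue-restricted; expressing tissues come from the largest
  gap in the sorted expression vector. Splicing entropy is Shannon entropy
  (bits) of isoform usage; per-sample summary is the median over genes with
  ≥ 2 expressed isoforms.

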