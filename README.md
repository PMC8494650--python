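# isoshift

Cell-type-specific **isoform shift** analysis for multi-platform single-cell
transcriptomics, modelled on the mouse primary motor cortex setting: deep
full-length (SMART-seq-style) data quantified at isoform resolution, 3′-end
droplet data quantified through transcript compatibility counts (TCCs), and
imaging-based spatial data (MERFISH-style) measuring a targeted gene panel
with cell positions, all sharing a three-level cell ontology
(class → subclass → cluster).

## The problem and the statistics

Most single-cell analyses stop at the gene level, but a gene can keep its
total expression constant between cell types while the *composition* of its
isoforms changes completely. `isoshift` detects and dissects exactly these
events:

- **Cluster-vs-complement testing.** For each feature *f* (gene, isoform, or
  TSS group) and each cell group *g*, a two-sided two-sample *t*-test on
  log1p-normalized expression between *g* and its complement, Bonferroni
  corrected within the comparison: significant iff
  *p*·*m* < α with α = 0.01 and *m* the number of features tested.
- **Gene-constant isoform shifts.** Report isoform *i* as a shift marker for
  group *g* iff *i* is significant and upregulated (mean_in > mean_out),
  expressed in ≥ 90 % of *g*'s cells, and its parent gene is **not**
  significant in the same comparison.
- **TSS-group regulation.** Transcripts sharing a transcription start site
  are summed into a cell-by-TSS matrix. A differential TSS group with no
  individually differential member indicates **transcriptional** regulation
  (promoter usage); differential members inside a non-differential TSS group
  indicate **post-transcriptional** regulation (splicing).
- **TCC extraction.** For 3′-end data, isoform counts are recovered only
  from *singleton* equivalence classes — the classes compatible with exactly
  one transcript (unique 3′ sequence).
- **Spatial extrapolation and depth.** Spatial gene markers are joined with
  full-length isoform markers per subclass; a pial boundary line is fitted
  to the upper convex hull of a slice, subclass centroid depths are
  normalized perpendicular distances, and per-isoform weighted least squares
  regresses subclass mean expression on depth (single-predictor *F*-test,
  Bonferroni; strict-monotonicity check for |slope| > 1.5).
- **Concordance and refinement.** Cross-platform per-group Pearson
  correlation of mean cells (common features, per-cell 1e6 normalization,
  log1p, per-feature scaling, 50 %-presence rule); NCA projection with a
  label-permutation overfitting control (chance purity Σ f²); and
  isoform-space reclustering of gene-derived clusters, gated by a
  Bonferroni-significant isoform on counts held out via count splitting.

A fully tested synthetic-data generator plants every effect kind
(gene-constant swaps, markers, sex effects, transcriptional and
post-transcriptional TSS effects, depth gradients, cluster splits) with
negative-binomial counts, library-size and mitochondrial variation,
equivalence classes, and layered slice geometry — and records the ground
truth for recovery testing.

## Worked example

`examples/01_gene_constant_shifts.py` plants five 0.8/0.2 → 0.2/0.8 isoform
proportion swaps (gene mean 10 counts/cell held constant) between a
glutamatergic and a GABAergic class of 400 cells each, and detects them:

```
feature_id group  mean_in  mean_out        p_adj
   g003-t2  glut 9.784116  6.892510 3.227421e-43
   g004-t2  glut 9.806916  7.132186 8.786980e-43
   g005-t2  glut 9.786197  6.952107 3.987260e-45
   g001-t1  gaba 9.852079  7.046398 3.147374e-46
   ...
   g005-t1  gaba 9.806533  7.027883 1.552684e-44

planted upregulated isoforms recovered: 5/5
```

Each row is an isoform significantly upregulated (log1p TPM means shown) in
a class whose parent gene shows no class difference — the signal a
gene-level analysis cannot see. Every planted swap is recovered in both
directions (the isoform that goes down in one class goes up in the other).
The other scripts in `examples/` walk through TSS regulation
classification, the spatial depth model, cross-platform concordance, and
projection/refinement, each printing the numbers it computes and what they
mean.

There is also a thin CLI for the same capabilities
(`isoshift simulate | preprocess | diffexp | spatial | crossplat |
batchcheck | pipeline`), e.g.:

```bash
isoshift simulate --config cfg.yaml --out data/
isoshift pipeline --config cfg.yaml --out run/
```

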