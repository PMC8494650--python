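# Methods

This note documents the statistical model behind `isoshift`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical conventions.

## Differential testing

All group-vs-complement comparisons use a two-sided two-sample *t*-test per
feature on log1p-normalized values (TPM for full-length data, CPM for
3′-end data — both normalize each cell to 10⁶ before log1p). The default is
the pooled-variance (Student) test; Welch is available via
`equal_var=False`. Degenerate cases, which arise constantly on sparse toy
matrices, are fixed by convention: both samples constant and equal → *t* = 0,
*p* = 1; constant and unequal → *t* = ±∞, *p* = 0.

Multiple testing uses Bonferroni with the family equal to the number of
features tested within one group-vs-complement comparison (not pooled
across groups): result tables are organized per level and group, and the
per-comparison family is the conservative reading. The significance level
is α = 0.01 throughout. Groups with fewer than 6 cells are skipped.

**Gene-constant shifts** report isoform *i* for group *g* iff adjusted
*p* < α, mean_in > mean_out (only upregulation is reported; the
downregulated partner surfaces as upregulated in the complement groups),
expressed fraction in *g* ≥ 0.9 (raw value > 0), and the parent gene's
adjusted *p* ≥ α at the same threshold (the symmetric reading of "not
significantly expressed"). The 90 % filter is applied as a reporting
filter after testing; the Bonferroni family is the tested features. Marker
detection is the same rule without the gene condition.

**TSS regulation.** The cell-by-TSS matrix sums raw isoform counts within
each TSS group and is then normalized like any other matrix. For a (TSS
group, class) pair: `tss_transcriptional` iff the TSS test is significant
and *every* member isoform test is not; `tss_post_transcriptional` rows are
the member isoforms that are significant while the TSS test is not. The
categories are mutually exclusive by construction. Because a TSS total is
the sum of its members, the transcriptional category is realized through
the power gap between a summed signal and its individual members — which is
also how the generator plants such effects (below). No expressed-fraction
filter is applied here; the rule is purely significance-based.

## Preprocessing

Full-length isoform counts are divided by transcript length before any
aggregation (long transcripts attract proportionally more reads; dividing
by length makes values proportional to molecule counts). Feature filtering
drops all-zero isoforms (the configurable reading of a vacuous
"fewer than one count / fewer than one cell" rule) and genes with
dispersion (variance/mean of summed isoform raw values across cells)
below 0.001, cascading to their isoforms; gene-level filtering with
cascade is the reading of "genes and their corresponding isoforms", and
the filter is idempotent. Cell QC keeps cells with total ≥ 250 and
mitochondrial fraction ≤ 10 % (full-length) or ≤ 21.5 % (3′-end); the
wording "fewer than / greater than" makes both boundaries inclusive-keep.

Highly variable features: dispersion = variance/mean of the supplied
(log1p) values; 20 equal-frequency bins by mean expression; within each bin
the dispersion is z-scored (subtract bin mean, divide by bin **standard
deviation** — the seurat-flavor implementation's formula; a description
that divides by the bin variance would make ranks incomparable across
bins); top 5,000 by normalized dispersion. Single-feature and
zero-variance bins get normalized dispersion 0.

TCC extraction keeps exactly the singleton equivalence classes and
relabels them to their transcript; a transcript appearing in two singleton
classes is an error (ambiguous map).

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
the sequencing process:

- **Counts**: per-gene mean from a log-normal (default median ≈ 2
  counts/cell, σ = 1), split across isoforms by a Dirichlet(5) draw, scaled
  by a per-cell log-normal size factor (CV 0.3), with NB(θ = 10) noise via a
  gamma–Poisson mixture. These dispersion and variation defaults are
  conventional for UMI-scale data, not fitted to any platform.
- **Mitochondrial content**: five single-isoform `mt-` genes receive, per
  cell, the expected share f/(1−f) of the non-mito total with
  f ~ Beta(2, 48) (mean ≈ 4 %).
- **Ontology and sexes**: cells follow the configured
  class/subclass/cluster table; sex is Bernoulli(½) per cell; batches cycle
  through the configured dates.
- **Planted effects** modify the expected-mean matrix only, so every effect
  holds *in expectation* and recovery is a statistical question:
  gene-constant swaps exchange the two leading isoform proportions between
  a group and its complement at fixed gene mean; markers and sex effects
  are fold changes on one isoform; post-transcriptional TSS effects swap
  proportions within a TSS group at fixed group total. Transcriptional TSS
  effects are a uniform fold on a TSS group of many low-abundance members
  (default 24 members at 0.0025 counts/cell, 4-fold): an a-priori power
  calculation (normal approximation: member *t* ≈ 30·√mean, so members sit
  near *t* ≈ 1.5 against a Bonferroni threshold ≈ 4.8 while the summed TSS
  signal sits near *t* ≈ 7.4 at 500 cells/class) makes the group signal
  detectable while members are individually underpowered — the only way a
  sum can be significant with non-significant members, and the realistic
  shape of promoter-level regulation among minor isoforms.
- **Equivalence classes**: unique-3′ transcripts (fraction `ec_structure`)
  get singleton classes; the rest of each gene shares one class; a lone
  leftover is promoted to unique so "singleton class" and the `unique3p`
  flag coincide exactly. Planted-effect genes get equal isoform lengths so
  count-space effects survive length normalization unchanged.
- **Spatial data**: subclasses occupy equal-height depth bands (y grows
  downward from the pia) in a slice that tapers 15 % per side toward depth,
  so the convex hull's upward-facing edges trace the pial surface. Each
  subclass gets a marker gene (5-fold); depth gradients make a panel gene's
  expected expression linear in the subclass's normalized band-centre
  depth, matching the downstream centroid normalization. Counts are
  Poisson.

What passing recovery tests does **not** show: the generator has no length
bias within genes, no read-level or fragment model, no doublets or ambient
RNA, no batch-specific expression shifts (batches differ only by label),
and isoform proportions that are constant across cells within a group.
Real-data performance depends on those nuisances.

## Spatial geometry and depth regression

The pial boundary line is fitted by OLS through the hull vertices of edges
whose outward normal points toward decreasing y ("upward", pia at low y —
the convention that makes "upper" well defined). The line is stored in
normalized general form ax + by + c = 0, so a fitted model can be carried
through rigid motions exactly (`DepthModel.transformed`); refitting after a
rotation would not commute with OLS, which minimizes vertical offsets.
Subclass depth = perpendicular centroid distance / maximum such distance
(deepest subclass ≡ 1).

Depth regression: response = per-subclass mean of the supplied values;
single-predictor WLS with the *F*-test of the slope (equivalent to the
squared slope *t*-test), Bonferroni over tested isoforms; only isoforms
with ≥ 90 % nonzero cells in every subclass are tested. The quoted design
"weights equal to the variance" upweights noisy subclasses — the opposite
of standard WLS — so the default here is inverse-variance weighting, with
`weights="variance"` reproducing the literal choice and `weights="equal"`
reducing exactly to OLS (used by the recovery checks). Zero-variance
subclasses get the largest finite weight of that feature. Monotonicity
(strict, ties break it) is evaluated only for |slope| > 1.5. The
representative slice is the one with the most cells.

## Cross-platform concordance

The pipeline is executed in the quoted order: common features → per-cell
1e6 → log1p → per-feature scaling (fitted per platform; a flag could share
parameters, and the per-platform choice is the default because platforms
have different technical scales). "Present" means raw count > 0, evaluated
per platform per group; the mean cell is computed on scaled values (the
last state before the mean-cell step). Batch pseudo-bulk profiles use
means of log1p CPM (the normalization is a documented choice; the source
procedure names only "gene counts").

## Projection and refinement

NCA (scikit-learn) on scaled values, 10 components, seeded; 2-D layouts
are visualization-only and outside any tested surface. The permutation
control permutes labels uniformly (seeded), refits, and scores the mean
fraction of same-label cells among 15 nearest neighbours; the chance rate
is Σ f² over label frequencies. The control is honest only when the
parameter count (features × components) is well below the cell count —
the benchmark uses 450 cells × 12 features.

Cluster refinement is statistics-gated, and the gate must survive the
selection effect of testing a partition discovered on the same data. The
counts are therefore split by binomial thinning into a discovery and a
validation half (count splitting; exact under Poisson, and a
Beta-Binomial variant via `split_dispersion` is exact under NB when the
dispersion is known). Discovery: log1p CPM, per-feature scaling, log
library size regressed out (depth leaves a zero-pattern signature that
otherwise dominates the partition), PCA to 10 components, kNN graph
(k = 15), Leiden at resolution 0.6 (seeded); `mt-` features are excluded as
technical. The two largest communities are candidates; the split is
accepted iff both have > 5 cells and ≥ 1 isoform is Bonferroni-significant
at α = 0.01 *on the validation half*. Effect sizes are differences of
subcluster means on the log1p scale averaged over significant features,
computed in parallel for genes (0 when nothing is significant). The
reclustering algorithm itself is a documented stand-in — any seeded
partitioner works — because the accept/reject decision is carried by the
held-out significance gate, not the geometry.

## Problem sizes and determinism

The test suite and acceptance benchmarks run on deliberately small
simulations (hundreds of cells, hundreds of genes; ~2,000 isoforms for
null calibration; 20 replicates for shift recovery), chosen so the whole
battery completes in a few minutes on one core while leaving wide
statistical margins. Every random draw derives from a single integer seed
through `numpy.random.SeedSequence` spawns, so identical configs and seeds
give bit-identical annotations, counts, TCCs and coordinates.

## Known limitations

Single alpha/Bonferroni only (an FDR hook would be a config switch);
Dirichlet-style proportion models and dual-platform EM quantification are
out of scope (matrices are consumed, not inferred from reads); the depth
model is linear — the monotonicity check exists precisely because a linear
fit can be significant without a monotone profile, and nonlinear depth
models are left as a hook.
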