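# Methods

This note documents the statistical models, the tunable parameters, the
synthetic-data generator, and the numerical and design choices behind
`crossmod`. It states no empirical result that the test suite does not
itself compute.

## Preprocessing

**Low-expression filter.** A gene is removed iff the fraction of samples
with TPM below `min_tpm` (default 10) is *strictly greater* than
`max_frac_below` (default 0.9). The strict inequality is deliberate: a gene
expressed at ≥ 10 TPM in exactly one of ten samples sits at the boundary
and is kept. The filter is idempotent and never changes the sample set.

**Batch correction.** Per-gene location/scale adjustment in the ComBat
family. Expression is standardized against a model containing batch
indicators and, by default, strain indicators (`covariates=True`), so that
biological signal is not absorbed into batch terms when strains are
unevenly distributed over batches; `--combat-no-covariates` reproduces the
covariate-free variant. With `eb=True` the per-batch locations get a normal
prior and the scales an inverse-gamma prior, hyperparameters by method of
moments across genes, solved by fixed-point iteration (tolerance 1e-6,
max 200 iterations); `eb=False` uses the raw per-batch moments and is exact
for a pure location shift. A single batch is an identity. Overall gene
means are preserved through the standardization mean. One caution at small
n: removing estimated batch means consumes residual degrees of freedom, so
per-gene group statistics after correction are inflated by a factor of
order `n_batches / n`; at the emulated 48-sample design this is < 5%.

**PCA.** Samples are observations, genes are variables, gene-centering only
(a `scale` flag standardizes). Components are oriented so the
largest-magnitude gene loading is positive, making scores reproducible.

## Differential expression

A deliberately simplified negative-binomial Wald test, standing in for
DESeq2 (which the pipeline does not attempt to reproduce):

* **Size factors** — median over all-positive genes of count / per-gene
  geometric mean, rescaled to geometric mean 1.
* **Dispersion** — per-gene method of moments on normalized counts
  (residual variance around strain×batch group means, solved from
  `var = μ + α μ²`, floored at 1e-8), then a trend `α(μ) = a0 + a1/μ` is
  fit across genes and **the trend value is used** (full shrinkage,
  `_trend_shrink` weight 1). Rationale: with ~12–19 samples per contrast
  the gene-wise estimates are far too noisy for a plug-in Wald test — in
  null simulations at the panel's design, gene-wise plug-in gave a type-I
  error of 0.088 and a 50/50 blend 0.0675, while the trend value gives
  0.049–0.058. Intermediate weights are available via the `dispersion_trend`
  machinery for data with genuinely heterogeneous dispersions.
* **Test** — NB log-linear GLM with intercept, strain indicator, batch
  indicators and log size factors as offset; Wald z on the strain
  coefficient against the normal tail; BH across tested genes. Genes whose
  NB fit fails fall back to Poisson (flagged `poisson`); genes with zero
  counts everywhere are flagged `untestable` and excluded from BH rather
  than assigned p = 1.
* **Design** — by default each strain is tested on its own samples plus all
  control samples (`joint=True` keeps the full panel in one design).

Not implemented, by design: Cox–Reid dispersion adjustment, LFC shrinkage,
independent filtering, outlier replacement.

## Co-expression modules

Unsigned weighted network `a_ij = |cor(x_i, x_j)|^β`. The soft power is
chosen as the smallest β whose **signed scale-free fit R²** reaches 0.85
(default grid 1..20; falls back to the best power with a warning).
The fit bins connectivities into 10 equal-occupancy bins and regresses
log10 of the empirical *density* in each bin (bin fraction / bin width) on
log10 of the bin's mean connectivity; with equal-count bins the density —
not the raw frequency, which is constant by construction — is the
meaningful p(k) estimate. R² is negated when the slope is positive.

Topological overlap uses the standard unsigned form with unit diagonal;
clustering is average linkage on `1 − TOM`. The tree is cut **statically**
at `0.995 × max merge height` (configurable, absolute heights accepted);
branches with ≥ `min_size` (default 30) genes become modules, everything
else is grey. This is the simple "tree" variant of dynamic tree cut — the
PAM-like "hybrid" variant with its deepSplit control is out of scope, and
the variant used by the original analysis is not stated anywhere we could
verify, so the fully specifiable one was chosen.

Module eigengenes are first principal components of the standardized
member-gene matrix, scaled to unit sample variance (ddof = 1) and oriented
so the mean correlation with member genes is nonnegative. Modules whose
eigengenes are closer than the merge height (1 − cor < 0.25) are merged
iteratively, largest-first label wins, eigengenes recomputed after every
merge.

Modules are named by the conventional WGCNA color sequence in decreasing
size order; label↔content correspondence with any particular published
module set is not meaningful.

## Strain association

Per module: one-way ANOVA of the eigengene over strains, BH across modules;
modules passing at α get Tukey–Kramer HSD contrasts (pooled within-group
variance, studentized-range tail, Kramer correction for unequal group
sizes). A strain is a **driver** when the module's BH-adjusted ANOVA p and
its Tukey contrast against the control are both < α (default 0.05).
Strains with one sample are excluded from the Tukey stage. The optional
`tukey_bh` switch additionally BH-adjusts the Tukey p-values across all
reported contrasts before the driver call — the stricter reading of
"reported p-values were adjusted"; it is off by default. ANOVA on fully
degenerate data (zero between- and within-group variance) returns F = 0,
p = 1 so module scans never crash on constant eigengenes.

## Enrichment

Hypergeometric upper tail `P[X ≥ k]` computed by log-space summation over
the support, BH across catalog sets. The universe defaults to the filtered
transcriptome, not the genome: the analyzed genes are the population from
which modules draw, and a genome universe would inflate every enrichment.
Regulon (TF-target) analysis is the same operation against a regulon GMT.

## Cross-species comparison

**Mapping policies.** `all_pairs` keeps every ortholog pair and is used for
set overlap, where a one-to-many gene legitimately lands its module in
multiple human genes. `one_to_one` keeps only genes unique in both
directions and is used for correlations, where duplicated observations
would pseudo-replicate.

**Overlap significance.** The observed Jaccard maps the mouse module
through `all_pairs` and compares with the human module. The null redraws
`|module|` genes without replacement from the union of all mouse module
genes (the stated universe; a flag switches to the full expressed set for
sensitivity analysis) and maps/scores each draw identically. The empirical
p uses the add-one estimator `(1 + #{J_null ≥ J_obs}) / (n_perm + 1)` —
never exactly zero, and a valid p-value. The universe is sorted internally
so p does not depend on input order; BH is applied across all module pairs.

**Perturbation model.** Ordinary least squares of log2 expression on an
intercept plus one indicator per mutant strain, control as reference, so
each β_i is the strain-i mean minus the control mean. Batch indicators are
off by default (matching the plain model; `with_batch` adds them). The
design must be full rank; collinear columns are named in the error.

**Concordance.** Pearson correlation with the t-based two-sided test over
the genes of a human module that carry an LFC value and a one-to-one β;
n < 3 or zero-variance inputs yield an `untestable` flag rather than an
exception. BH runs jointly across all (strain × module × region) testable
results; rows with adjusted p > 0.05 are reported but marked
non-significant.

## Synthetic data generator

The generator emulates the study design this pipeline targets: 48 RNA-seq
samples — five late-onset perturbation strains × 6 replicates, APP/PS1 × 5,
B6 controls × 13 — in three batches (36 / 8 / 4, with controls split 6/7
between batches 1 and 2).

Latent log2 expression of gene g in sample j:

```
x_gj = baseline_g + loading · (z_m(g),j + δ_m(g),strain(j)) + b_g,batch(j) + ε_gj
```

* `baseline_g ~ U(4, 9)` log2 units (desk-scale stand-in for a filtered
  brain transcriptome; 1,000 genes by default — 5 modules of 80/70/60/50/40
  plus 700 background genes);
* `z_m,j ~ N(0, signal_sd²)` the module eigengene signal (default sd 1);
* `δ` the planted per-(module, strain) shift; by default each module gets
  one driver strain (round-robin) with |δ| ~ U(0.3, 1.5) and random sign —
  a calibration choice, the effect-size scale of real strains being
  unknown;
* `b ~ N(0, 0.3²)` per gene × batch;
* `ε ~ N(0, σ²)` with σ set from the target within-module correlation r via
  `σ = loading · signal_sd · √((1−r)/r)` (default r = 0.7), or given
  directly.

Background genes carry no module signal; 25 per strain (by default)
receive an independent per-gene effect with |LFC| ~ U(1, 2) to exercise the
DE stage. TPM = `2^x − 1` clipped at zero with columns rescaled to a
constant sum; counts are gamma–Poisson around TPM × library size
(U(0.8M, 1.6M)) with dispersion 0.05.

The human reference maps 90% of mouse genes one-to-one (5% of those get a
second partner, forcing the mapping policy to be exercised); each human
module is the image of one mouse module plus 20% random contamination
(which controls the planted Jaccard below 1). Human LFC per region is
standard normal noise except where a concordance target is planted: for
the driver strain s of module m, LFC over the module genes carrying a
one-to-one β is `r · zscore(β_s) + √(1−r²) · noise` with r = 0.5 by
default, so the correlation realized over exactly the genes the
concordance test uses is ≈ r. Genes in several human modules keep the
first-planted value. `generate_human_reference` records the planted
targets in `truth.r_target`.

All generation is deterministic given a seed (one `numpy` Generator per
call); the pipeline derives stage-specific substreams from the global seed
via `SeedSequence`, so changing one stage's randomness leaves upstream
outputs unchanged.

### What a green test does and does not establish

The generator's Gaussian log-scale world has no gene-length or GC effects,
no count outliers, no dispersion trends beyond the NB mean–variance
relation, no correlated batch×strain confounding beyond what the design
implies, and modules with homogeneous loadings. Green recovery tests
establish that the implementation recovers what it is mathematically
supposed to recover — not that the pipeline is robust to the pathologies
of real RNA-seq.

Two real phenomena the generator *does* reproduce, and which bound what
recovery tests can promise:

* **Compositional renormalization.** TPM columns sum to a constant, so a
  strain that up-regulates one module depresses every other gene's TPM in
  that strain's samples. When the shifted module is a large fraction of the
  transcriptome this leaks detectable pseudo-effects into unrelated
  modules and genes. This is a property of relative-abundance data, not a
  bug; recovery worlds dilute planted modules below ~6% of the
  transcriptome.
* **Shared eigengene sampling noise.** A module's per-gene effect estimates
  all contain the same `loading · (z̄_strain − z̄_control)` term, whose sd
  is ≈ 0.49·signal_sd at 6-vs-13 samples. It attenuates recovered
  concordance (a planted r = 0.5 is typically estimated in the 0.35–0.5
  range at n = 6) and, because it mimics a module-level strain effect, it
  can make a *wrong* strain appear concordant with a matched human module.
  Concordance calibration is therefore stated in terms of multi-seed means,
  and null calibration uses worlds with no planted concordance anywhere.

## Numerical choices

* BH ties broken by original index (stable sort); result is tie-invariant.
  BH is *not* idempotent on tied adjusted values — re-adjustment can only
  increase values, which is the property the tests assert.
* Pearson |r| ≥ 1 − 1e-12 is treated as exact collinearity (p = 0);
  variance below 1e-10 of the data scale is degenerate input.
* Tukey with zero pooled variance: p = 1 for equal means, p = 0 otherwise;
  p clamped to [0, 1] after the studentized-range tail.
* TOM is symmetrized against float drift and clipped to [0, 1].
* Counts with dispersion ≤ 1e-12 are drawn Poisson directly.
* Empirical overlap p-values are superuniform in steps on the discrete
  Jaccard lattice; uniformity holds (and is tested) for modules large
  enough that the lattice is fine relative to 1/√n_pairs.

## Known limitations

* The DE stage is not DESeq2 and does not aim to match its gene lists;
  only its calibration and power properties are tested.
* Static branch cut, not hybrid dynamic tree cut: isolated small blocks are
  reliably grey, but a block one gene short of `min_size` can absorb a
  straggler background gene and cross the threshold in noisy worlds.
* Module labels (colors) are arbitrary size-rank names; only memberships
  are comparable across runs.
* One CPU; no block-wise decomposition — matrices beyond ~30,000 genes
  will not fit the dense TOM path.
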