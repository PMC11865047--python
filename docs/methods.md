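# Methods

This note documents the models, parameter choices and numerical details
behind `mucinsig`, and what the synthetic-cohort experiments do and do not
establish about real data.

## Synthetic cohort model

Counts for cell *i*, gene *g* are negative binomial with mean

    mu_ig = d_i * p_g(lineage_i, condition_i) * dosage_g(clone_i) * f_{b(i),g}

and shared dispersion theta (`nb_dispersion`, default 10; variance
mu + mu^2/theta). Components:

- **Depth** d_i ~ Uniform(`depth_range`), default 1,500–3,000 expected
  counts, spanning typical droplet scRNA-seq depths after QC.
- **Lineage profiles** p_g: a common log-normal base weight per gene
  (sigma = 1), modulated per lineage by an independent log-normal factor
  (sigma = 0.45); each lineage's marker genes (goblet/epithelial, immune,
  stromal panels) are boosted 8x in their own lineage and suppressed to
  0.05x elsewhere. Profiles are normalized to sum to 1 before the other
  factors apply, so differential factors act multiplicatively on relative
  abundance.
- **Condition programs**: four pairwise-disjoint gene lists (30 genes each
  by default) — normal-specific, shared-tumor, AMN-unique, PMP-unique —
  multiplied by 2^delta (delta = `de_log2_effect` = 1.0) in epithelial
  cells of the matching condition. Program genes draw their baseline from
  a narrow log-normal centered at 4x the typical gene so planted effects
  act on reliably detected genes, as real secretory/differentiation
  markers are.
- **CNV dosage**: states map to copies {1: leakage, 2: 1, 3: 2 (neutral),
  4: 3, 5: 4, 6: 6} and dosage = copies/2. Complete loss uses a leakage
  floor of 0.02 rather than exact zero so log-space operations stay
  finite; the constant is exported as `STATE_DOSAGE`.
- **Batch factor** f_{b,g}: per-(batch, gene) log-normal with
  sigma = `batch_effect_sd` = 0.3. In log space this is an additive
  per-batch gene offset — exactly the structure a centroid-based
  correction can remove, and deliberately smaller than lineage separation;
  batch effects that exceed biological separation are not identifiable by
  any mixing-based correction and are out of scope.
- **Genome**: 4 chromosomes x 60 Mb with one gene per 100 kb (2,400
  genes), so a 10 Mb window holds ~100 genes. The truth window grid is
  produced by the same windowing routine the CNV module uses; bundled
  clone segments are aligned to that grid so per-window truth states are
  unambiguous. Named mitochondrial (MT-) and ribosomal (RPS/RPL) genes are
  woven into the layout to exercise the QC and DE exclusion paths.

The bulk validation cohort (63 samples by default) is log2-scale:
background N(5, 1) per gene, plus purity x activity x 2.0 on the
shared-tumor genes (goblet activity), the PMP-unique genes (metastasis
activity) and — scaled by 1 − purity — the normal-specific genes, plus
N(0, 0.4) noise. Purity ~ Beta(28, 12) (mean 0.7, sd ~0.07), reflecting a
pathologist-curated tumor cohort; a wide purity spread would itself couple
the two programs and confound the independence condition. With the
co-expression flag both tumor activities equal one per-sample latent
N(1, 0.4) factor; otherwise they are independent draws.

The protein table emulates only the downstream per-protein p-values: decoy
and null-target p-values are Uniform(0, 1]; planted strong targets draw
-log10 p ~ Uniform(8, 12), i.e. identifications far below any plausible
decoy minimum, as confident spectrum matches are.

**What the generator does not emulate:** ambient RNA, doublets (the QC
doublet scorer is exercised on explicitly constructed cell-pair sums),
per-gene dispersion heterogeneity, cell-cycle structure, spatial effects,
batch-by-lineage interactions, and read-level artifacts. Recovery on this
generator therefore demonstrates internal consistency of the pipeline
under its stated noise model, not performance on any real cohort.

## Pipeline numerical choices

- **Normalization**: log1p(1e4 * count / total). The scaled layer
  regresses each gene's log values on total counts (OLS), standardizes the
  residuals and caps them at ±10; zero-variance genes scale to 0. This
  replaces variance-stabilizing transforms because every downstream test
  here is rank-based or works on the log layer.
- **QC**: cells with fewer than 200 detected genes or more than 20%
  mitochondrial counts are dropped. The doublet score is each cell's best
  Pearson correlation to seeded synthetic cell-pair averages, with the top
  `doublet_quantile` removed; the default quantile is 0.0 because the
  generator plants no doublets, which also makes the QC filter idempotent
  at defaults (a quantile cut re-applied would trim again).
- **Batch correction**: soft k-means in PC space (K = 10, softmax scale
  0.5 x mean nearest-centroid distance) with a batch-diversity penalty
  theta = 2 on the assignment logits, updated in incremental blocks of 5%
  of cells — full recomputation oscillates between batch-pure states.
  Each iteration subtracts every cell's responsibility-weighted
  (batch-centroid − cluster-centroid) offset; iterate to movement < 1e-6
  or 30 iterations. With one batch the input is returned unchanged; with
  one cluster and two shifted copies the shift is removed exactly.
- **Clustering**: SNN graph from the 15 nearest neighbors (Jaccard
  weights, pruned below 1/15), Leiden RBConfiguration partition at
  resolution 1.0 with a fixed seed; ties resolve by the seeded optimizer
  order.
- **Assignment**: Spearman correlation over the union of reference marker
  genes (>= 20 genes required), argmax with alphabetical tie-break, then a
  fine-tuning pass restricted to the top two candidates' own markers.
  Correlations are rounded at 1e-12 before argmax so floating-point noise
  cannot flip ties.
- **Abundance GLM**: binomial with logit link at the *sample* level
  (cells-of-type vs other cells), avoiding pseudo-replication across
  cells; Wald z per condition contrast, Benjamini–Hochberg across cell
  types. Complete separation (|coef| > 15 or non-finite SE) triggers a
  flagged refit with 0.5 pseudo-counts.
- **CNV**: genes below mean 1.0 CP10K are excluded (their log ratios
  attenuate toward zero); the log layer is rescaled to base 2 and centered
  on the reference-cell mean (>= 30 reference cells), clipped at ±3.
  Window scores are sqrt(reference-mean)-weighted means — weighting favors
  well-measured genes without letting one gene dominate — followed by
  per-cell median re-centering. State thresholds (-1.5, -0.25, ±0.25,
  0.8, 1.4) are the midpoint calibration of log2(copies/2) under the
  dosage model above; they are configurable because real data attenuate
  more. FGA weights windows by bp length by default ("fraction of genome"
  is a length statement); gene-count weighting is exposed.
- **Consensus and trees**: modal state per window with ties resolved
  toward neutral; bp-weighted L1 distance between state vectors;
  neighbor joining (scikit-bio) with negative branch lengths clamped to 0,
  leaves sorted for determinism, re-rooted at the diploid leaf's
  attachment. Branch lengths are in weighted-state units and are not
  comparable across distance choices.
- **Wilcoxon DE**: asymptotic Mann–Whitney with tie correction; for
  pooled group sizes <= 16 the p-value is an exhaustive permutation
  enumeration (two-sided as P(|R − E[R]| >= |r_obs − E[R]|) with
  midranks), which handles ties exactly. log2FC =
  log2((mean(expm1 A)+1)/(mean(expm1 B)+1)); all-tied genes get p = 1.
  The normal-specific signature requires significance against *both*
  tumor conditions (the disjointness-preserving reading); the looser
  either-condition rule is a flag, with tumor-claimed genes removed from
  the normal set to restore disjointness.
- **Enrichment**: Gaussian-kernel ECDF with bandwidth sd/4 per gene
  (`kcdf="gaussian"`), genes ranked per unit, in-set walk steps weighted
  by |rank − (p+1)/2|^tau (tau = 1), score = max positive + max negative
  walk deviation. The empirical-ECDF variant (`kcdf="ecdf"`) is exactly
  invariant to per-gene monotone transforms; the Gaussian kernel is only
  approximately so. Percent-positive counts strictly positive scores;
  zeros count negative.
- **Decoy filter**: multiplicative reading of "factor-fold lower log p"
  (log10 p_target <= factor x log10 p_top-decoy), which is invariant to
  the log base; the additive reading (subtract `factor` log10 units) is a
  switch. Equality at the threshold keeps the protein.

## Problem sizes

The bundled experiments run at desk scale, chosen so each recovery test is
comfortably powered: 3,000 cells for the batch-mixing contract, 2,000
cells for assignment accuracy, 2,000-count depth with ~100-gene windows
for CNV recovery, 20 samples for FGA, 100 seeds x 50 cells/site for tree
topology, 200 cells/condition for signature recovery, 63-sample bulk
cohorts, and 300–500 replicates for calibration checks. The acceptance
script uses 50-seed versions of the multi-seed experiments.

## Known limitations

- Expression-CNV has no HMM smoothing or per-chromosome baseline model;
  mixed windows (segment boundaries inside a window) are called by their
  dominant dosage.
- The GSVA-style score is a faithful rank-walk implementation but is not
  bit-compatible with any external implementation's defaults.
- The soft-k-means correction removes additive per-batch offsets in PC
  space; batch effects interacting with lineage or nonlinear distortions
  are outside its contract.
- Tukey HSD assumes balanced-ish groups through the studentized-range
  quantile with the harmonic mean handled by the underlying routine;
  heavily unbalanced designs deserve a mixed model instead.
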