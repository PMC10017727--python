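# Methods notes

This note records the modelling choices behind `phenet`, the defaults and
why they were chosen, and what the synthetic benchmarks do and do not show.

## Phenotype network features

**Node features.** ROI-mean gray-matter density is the arithmetic mean of a
density volume over atlas voxels, in voxel-index space. The package does no
registration or resampling; the caller must supply co-registered density and
atlas arrays. Label 0 is background. A packaged 116-name AAL label list
(`phenet.io.aal116_names`) fixes the canonical feature order.

**Edge features.** FC is the Pearson correlation of ROI-mean BOLD series
(series are z-scored first; Pearson is invariant to that, but it mirrors the
usual preprocessing convention). The per-node statistic is

    CC(i) = 2/(k_i(k_i-1)) * sum over unordered neighbour pairs {j,h}
            of  w̄_ij * w̄_ih * w̄_jh,       w̄ = w / max(w),

with CC(i) = 0 when k_i < 2. Three choices deserve comment:

* *Triple product, not geometric mean.* The common Onnela statistic uses the
  cube root of the same product. The plain product is implemented as the
  default because it is the exact form of the statistic this package
  targets; the Onnela variant is available via `geometric_mean=True`. Both
  coincide on binary graphs, where the statistic reduces to the classical
  clustering coefficient (cross-checked against networkx in the tests).
* *Negative correlations.* The max-weight scaling presumes nonnegative
  weights. Default: absolute value of the FC matrix before scaling
  (`negative_weights="abs"`); clipping negatives to zero is available. With
  either choice, scaled weights lie in [0, 1] and so does CC.
* *No thresholding by default.* The FC network is kept fully weighted
  (k_i = d−1 for correlation-built networks); an optional proportional
  threshold exists but is off, since sparsification is a study-level choice,
  not part of the statistic. An all-zero network yields CC = 0 with a
  warning rather than an error (max(w) is undefined there).

`top_k_edges` sorts incident edges by signed weight (largest connection
values first) with ROI-name tie-breaks; magnitude sorting is an option.

## Association model

The objective (see README for the formula) couples M per-modality ridge-free
least-squares fits through the L2,1 row penalty and adds, per modality, the
Laplacian quadratic λ₂ wᵀXᵀLXw, where L = D − S comes from the binary
same-stage similarity. The quadratic equals half the pairwise sum
Σ_ij (wᵀx_i − wᵀx_j)² S_ij, an identity the test suite verifies directly.
The Laplacian is unnormalized by design; λ₂ absorbs its scale. The
objective carries the Laplacian term with no factor ½, so the gradient
contribution is 2λ₂ XᵀLXw.

**Intercept and scaling.** The objective has no intercept. On raw,
positive-mean density features a no-intercept linear model would spend most
of its capacity on the mean, so each feature column is z-scored with
*training-fold* statistics and mean(y_train) is used as the per-modality
intercept at prediction time. y itself is not rescaled: RMSE stays on the
0–2 genotype scale. Constant columns get a unit divisor and a warning.

**Solver.** Accelerated proximal gradient with Nesterov momentum. The
smooth part is precomputed in d×d form (A_m = X_mᵀ(I + 2λ₂L)X_m,
b_m = X_mᵀy), so per-iteration cost is O(d²M) regardless of N. The step
starts at 1/L̂ with L̂ from power iteration on the largest A_m and backtracks
by halving against the quadratic majorization; a function-value restart
resets momentum whenever the objective would rise, so the recorded trace is
non-increasing. Convergence: relative objective change ≤ tol (default 1e-6,
max_iter 1000). The row prox is the group soft-threshold
max(0, 1 − τ/‖v_j‖)·v_j. Correctness anchors: the solver matches a 10⁶-step
plain proximal-gradient oracle to ~1e-12 relative on small instances; the
solution is exactly 0 iff λ₁ ≥ max_j ‖[X^1ᵀy … X^Mᵀy]_j‖₂
(`lambda_max`); with λ₂ = 0 the MSD code path is bit-identical to the
non-MSD one.

**Variants.** SM/MSD-SM take one modality (L2,1 with M=1 is the lasso);
CM/MSD-CM concatenate all modalities into a single 2d-column block, again
lasso; MM/MSD-MM are multi-task. Variants without the MSD prefix force
λ₂ = 0 at fit time regardless of the configured value.

## Evaluation protocol

Folds are stratified by diagnosis stage (round-robin within stage after a
seeded shuffle) because severe-stage groups can be small enough that
unstratified folds lose a class entirely. Repeat r uses seed + r. Inside
each outer fold, an inner k-fold CV over the λ grid picks the pair
minimizing mean inner-test RMSE, averaged over modalities for multi-task
variants (RMSE because it is the fitted loss; per-modality selection is a
config option). The model is refit on the full outer-training part. All
standardization happens inside each fit from that fit's training rows, so
no test-fold information can reach selection or weights — the test suite
checks this by corrupting test-fold responses and asserting bit-identical
selected λs and training-fold weights.

ROI ranking averages |w| over all outer folds and repeats; absolute values
prevent sign flips across folds from cancelling a consistently selected
region (signed means are reported alongside). SNP screening reruns the full
nested CV per SNP column, skipping monomorphic columns. Sensitivity grids
deliberately skip inner selection: each (λ₁, λ₂) cell is scored by plain
k-fold CV with those values held fixed.

The default λ ladder is the 12-value half-decade sequence 10⁻⁵ … 3 for both
parameters. The packaged benchmark studies (`phenet.benchmarks`) restrict
λ₁ to the ladder's upper half (3·10⁻² … 3) and λ₂ to five points
(10⁻⁵ … 3·10⁻¹): on the benchmark cohorts the inner CV never selects below
that range (sparser-than-RMSE-optimal solutions only appear above λ₁ ≈ 1),
and the restriction cuts the grid sixfold, which is what keeps repeated
nested CV at d = 116 tractable on a single core.

## Synthetic cohort design

The generator encodes the causal story the model assumes, with genotype as
the cause and imaging features as effects (the model regresses in the
phenotype→genotype direction, as association models do):

* genotype: Binomial(2, maf) minor-allele counts (Hardy–Weinberg), default
  maf 0.3 — a common-variant frequency typical of candidate SNPs;
* stages: a latent severity score `stage_assoc · g + logistic noise` is cut
  at the cumulative stage proportions (default 0.36/0.44/0.20, a pooled
  two-site mix), so marginal stage counts are exact while severer stages
  are enriched for risk-allele carriers. `stage_assoc = 1` (≈ e-fold odds
  per allele) reflects that a risk variant co-varies with clinical
  severity. This coupling is essential, not decorative: the Laplacian term
  only rewards pulling same-stage predictions together if stage actually
  carries information about the response, so a generator with
  genotype-independent stages cannot exhibit the MSD advantage at all
  (with `stage_assoc = 0` the generator produces exactly that null);
* features: X^m = β·g·c^m on a shared support of s rows (c^m ~ N(1, 0.1²)
  per modality), plus δ·μ_stage with per-stage mean profiles μ ~ N(0,1),
  plus N(0, σ²) noise. Defaults β = 0.5, σ = 1, s = 10, d = 116,
  N = 150. The stage shift default is δ = 0.3 feature-sd: case-control
  gray-matter differences in depression are subtle (effect sizes well under
  0.5), and a shift at noise magnitude would make every feature a
  stage-confound of comparable strength to the causal signal.

Raw-level fixtures: BOLD series are sampled from equicorrelated community
blocks whose within-block correlation rises with stage severity, and
volume fixtures are contiguous labelled blocks with known region means —
both exist to exercise the feature-construction path end to end with
known ground truth.

**What the generator does not emulate:** spatial voxel correlation, site
and scanner effects, hemodynamics, LD between SNPs, non-Gaussian noise, and
any real relation between a subject's feature matrix and their simulated
time series. Passing benchmarks therefore show the pipeline recovers the
structure it assumes at realistic sizes — not that the same numbers would
hold on a real cohort.

## Benchmark studies

* **Support recovery** (defaults, 10 seeds): repeated (5×) nested 5-fold CV
  with MSD-MM; ROIs ranked by CV-averaged |w| summed over modalities; F1 of
  the top-10 set against the planted support. Mean F1 ≈ 0.85–0.9, and
  causal rows carry several times the averaged weight of null rows.
* **Variant comparison** (`SimulationConfig.weak_association`: β = 0.25,
  δ = 1.0, stage_assoc = 1.5, 10 seeds, paired folds): emulates the
  weak-association regime candidate-SNP studies operate in, where
  out-of-sample CC sits well below the strong-signal ceiling and
  regularization choices separate the variants. Orderings observed:
  MSD-MM > MM (gap ≈ +0.04–0.06 CC) and MM ≥ SM on average; with stage
  labels permuted the MSD−MM gap collapses to selection noise (|gap|
  within 2 paired sd of zero). At the generator's default strong signal
  the Laplacian has nothing to add and the gap is ≈ 0 — the advantage is a
  weak-signal phenomenon, which is exactly the regime the method is for.

## Numerical and degenerate-input conventions

* Pearson CC of a constant prediction vector is reported as 0 with a
  degenerate flag (not NaN), so saturated-λ₁ cells in sensitivity grids
  stay finite.
* Inner-CV score ties break toward the smallest (λ₁, λ₂) pair in grid
  order (deterministic).
* A 50/50 allele-frequency tie takes the lexicographically smaller allele
  as major; missing genotype calls code as NaN and are flagged for
  listwise deletion per SNP.
* HAM-D scores 9–19 fall between the control ceiling and the
  moderate-depression floor and are returned `unclassified`; the CLI drops
  such subjects with a warning.
* Feature tables serialize at 17 significant digits and are parsed with
  correctly rounding `float()`, so write→read round-trips are bit-exact;
  CLI manifests contain no timestamps, making reruns byte-identical.

## Known limitations

* Single-SNP response only; no multivariate or multi-locus models.
* No covariate adjustment (age, sex, site) and no Fisher-z or thresholding
  options on FC beyond the proportional one.
* The solver assumes the smooth part fits in d×d Gram form; for d far
  beyond a few thousand a matrix-free variant would be needed.
* Screening reports raw per-SNP CC with no multiplicity correction.
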