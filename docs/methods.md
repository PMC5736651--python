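# Methods

## Model overview

The package models neuroanatomical variation in a developmental cohort as
a low-dimensional linear manifold per morphometric metric, learned by
neighbourhood-preserving embedding (NPE) over a supervised neighbour
graph, and uses the joint manifold to predict age and sex. The stages,
each fit strictly on training subjects:

1. optional global-scale correction of each metric's features;
2. mean-centring and SVD reduction retaining a variance fraction;
3. supervised k-nearest-neighbour graph from image x age similarity under
   sex-match and site-mismatch masks;
4. locally-linear reconstruction weights `W` over the graph;
5. the NPE generalized eigenproblem for the projection `P`;
6. an orthogonal rotation aligning axis 1 with age, axis 2 with sex;
7. concatenation of per-metric coordinates, then Gaussian-process age
   regression and linear-discriminant sex classification.

Assumptions worth stating: morphometric variation relevant to age and sex
is captured by *linear* structure after SVD reduction (the supervised
graph is what injects the nonlinearity of neighbourhood selection); sex is
a two-level label; ages are positive and on a common scale in years; and
feature columns are comparable across subjects (registered voxels or
matched vertices) so that Euclidean distance is meaningful.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 10 | neighbours per subject; small enough to stay local, large enough for stable weights |
| `d` | 3 | manifold dimensions per metric; axes 1-2 carry age/sex after rotation |
| `variance_retained` | 0.95 | SVD cut computed on squared singular values of the mean-centred matrix (features are never z-scored) |
| `image_bandwidth` σ | auto | median heuristic: σ² = median nonzero squared pairwise distance, pinning the median pair at exp(−1) |
| `age_bandwidth` τ | auto | median nonzero absolute pairwise age difference (the nonzero restriction keeps the kernel defined when many ages tie) |
| `combination_mode` | product | C = A∘a; a weighted sum (λA + (1−λ)a, image masks re-applied) is available |
| `use_site_constraint` | on | zero same-site similarities so neighbourhoods cross scanners; if a subject is left with no eligible neighbour the graph is rebuilt without the site mask (small sites can otherwise be starved) |
| `global_scale_correction` | off | per-feature OLS residualization against the metric's covariate (ICV / total area / mean thickness); a ratio variant exists for sensitivity analysis |
| `n_folds` | 10 | CV folds, stratified by sex x age-decile (plain shuffled folds by config) |
| `gp_restarts` | 3 | marginal-likelihood restarts of the GP fit, seeded |

Neighbour selection is directed (no symmetrization): the reconstruction
step needs each subject's own neighbour set, and mutual-kNN would shrink
eligibility under the site mask. Ties in combined score break toward the
smaller subject index; rows with fewer than `k` eligible neighbours are
flagged, not fatal.

## Numerical choices

- **Reconstruction weights.** Row `i` solves the local Gram system
  `G w = 1`, `w` normalized to sum 1, with `G = Z Zᵀ`, `Z` the neighbour
  differences. When `cond(G) > 1e12` (inevitable when `k` exceeds the
  local intrinsic dimension) the diagonal is inflated by
  `ridge·trace(G)/k`, ridge default `1e-3`, and the row is flagged in the
  diagnostics. For data lying exactly on a low-dimensional linear
  manifold the ridge is the only error source; a weaker ridge recovers
  essentially exact affine reconstructions.
- **Eigenproblem.** `XᵀMX p = λ XᵀX p` with `M = (I−W)ᵀ(I−W)` is solved
  as a symmetric-definite pencil after adding `1e-9·mean(diag)·I` to the
  right-hand side. Columns of `P` are unit-norm with the
  largest-magnitude entry positive, making serialized models reproducible
  across eigensolver backends. With mean-centred data the constant
  direction is outside the column space, so no further eigenvector
  rejection is needed.
- **Axis rotation.** Axis 1 is the exact maximizer of |corr(Y·r, age)|
  over unit directions — the OLS coefficient direction of age on the
  centred coordinates (fitted values of a least-squares fit have maximal
  correlation with the response among linear combinations of the
  columns). Axis 2 maximizes the sex correlation by the same argument
  restricted to the orthogonal complement of axis 1. Remaining columns
  complete the basis by Gram–Schmidt over canonical axes, smallest index
  first; signs make both target correlations positive. A
  standardized-coordinate variant of axis 1 would not be the exact argmax
  over rotations of Y itself, which is why the unstandardized direction
  is used.
- **Predictors.** GP kernel: constant × squared-exponential (isotropic
  length-scale) + white noise, noise variance floored at `1e-6`;
  features standardized with training statistics, zero-variance columns
  dropped (detected with a relative `1e-12` tolerance — a "constant"
  column retains cancellation noise from mean subtraction). LDA uses
  empirical priors and the exact pooled covariance; Ledoit–Wolf shrinkage
  is switched on only when its condition number exceeds `1e8`.
- **Degenerate inputs.** Constant matrices, constant covariates,
  all-equal ages with auto bandwidth, single-class training labels and
  empty neighbour rows are hard errors with named subjects/columns;
  constant training age short-circuits the GP to a constant predictor.
- **Determinism.** All randomness flows from one integer seed
  (`RunConfig.random_seed` / `GeneratorSpec.seed`); two runs of the
  evaluation write byte-identical JSON.

## Cross-validation and leakage

Folds are stratified by sex crossed with age decile (coarser quantiles
when the cohort is small; one re-randomization if a training fold ends up
single-sex, then an error). Within each fold every statistic — scale
correction, SVD mean/basis, graph bandwidths, weights, projection,
rotation, predictor hyperparameters — is refit on the training subjects
only; held-out subjects are projected with the frozen maps. A SHA-256
fingerprint over all fitted arrays supports the audit that training-fold
parameters are bit-identical under any permutation of held-out ages and
sexes. Pooled out-of-fold predictions give MAE, the Pearson correlation
of predicted versus chronological age, classification accuracy, an
age-binned table (age-ordered bins as equal as divisibility allows), a
per-site table, and a one-way ANOVA of absolute error over sites. The
brain-age-gap/cognition analysis residualizes each score on age, sex and
socioeconomic status, regresses the residual on the predicted-age error,
and reports per-score R², F(1, n−2), p and Bonferroni significance
across scores (correction method configurable).

Whether prediction consumes rotated or unrotated coordinates is
immaterial for the GP (rotation-invariant kernel) and LDA; the rotated
coordinates are used so that serialized coordinates and plots share one
frame. The joint PCA of the concatenated coordinates exists for
visualisation and reporting; predictors use the concatenated coordinates
themselves.

## Synthetic cohorts and what they show

The generator emulates the statistical structure of a multi-site
paediatric morphometry study without image geometry. Per metric, the
feature row is

```
x_i = g_i (mu + b_age t_age,i u_age + b_sex t_sex,i u_sex + Σ_l z_il v_l)
      + delta_site(i) + eps ,
```

with smooth (moving-average) unit pattern vectors, expression scores
`t_age,i = age_i + eta_i`, `t_sex,i = sex_i + nu_i` carrying
subject-level noise, and a global scale
`g_i = 1 + 0.01·age_i + gamma_sex·sex_i + N(0, 0.04²)` that multiplies
the signal (so scale correction genuinely interacts with it). Sex enters
`g` for volume and area (head-size dimorphism, ~10% between means) but
the spatial pattern for thickness — so correcting volume/area for ICV or
total area removes most of their sex signal while thickness keeps its
own, reproducing the qualitative ordering expected of global-scale
correction. Covariates (ICV mm³, total area mm², mean thickness mm)
are fixed multiples of the metric's true scale. Cognitive scores depend
on age, sex and SES plus independent noise — null with respect to the
brain patterns by construction.

The committed benchmark (`default_recovery_spec()`: n = 600, three
400-feature metrics, 4 sites, ages 3–21 y) is calibrated through the
score variances (eta sd 1.05 y per metric, nu sd 1.55 for thickness)
chosen from the closed-form posterior so that an oracle linear model on
the stored latent scores reaches an age MAE near 0.5 y and the sex Bayes
accuracy is near 97%. Benchmark sizes were chosen so the full evaluation
runs in minutes on one CPU.

What passing tests on these cohorts demonstrates: the pipeline recovers
planted low-dimensional structure, respects its masks, does not leak
across folds, and degrades to chance when the planted effects are
removed. What they do not demonstrate: performance on real images —
the generator has no spatial geometry, no registration error, no
heteroscedastic or spatially correlated noise beyond the smoothing
window, no age–site confounding, and linear (not maturational-curve)
age effects. Numbers obtained on synthetic cohorts are therefore
internal-consistency results, not forecasts of accuracy on any real
population.

## Known limitations

- No kernel/nonlinear NPE variants; no handling of subjects missing one
  metric at transform time.
- The site constraint can starve subjects in cohorts with one dominant
  site; the automatic fallback drops the constraint for the whole graph
  rather than per subject.
- Exact cohorts behind data-usage agreements are out of reach here, so
  tolerances on the embedding internals are validated against
  independent oracles (constrained least-squares, Rayleigh brute force,
  rotation grid) rather than against any external implementation.
- The cognition regression is two-stage OLS; it does not propagate
  uncertainty from the first-stage residualization.
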