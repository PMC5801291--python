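# Methods

`ppmcompare` implements and compares two families of second-level (group)
inference for fMRI contrast images under a one-sample design, together with
the synthetic-data and evaluation machinery needed to study their behavior
without scanner data.

## Model and procedures

### Group GLM

Each subject contributes one 3-D contrast image; per voxel v the model is
`x_iv = beta_v + e_iv`, `e_iv ~ N(0, sigma_v^2)` across subjects
i = 1..n.  `fit_group_glm` returns the sample mean `beta_hat_v`, the
unbiased variance (divisor n−1), and `t_v = beta_hat_v / sqrt(var_v / n)`
with df = n−1.  Zero-variance voxels get t = 0 when the mean is also zero,
and are flagged degenerate (t = ±inf) otherwise; degenerate voxels are
excluded from smoothness and prior estimation.

### Classical branch: random-field-theory FWE

Smoothness of the residual field is estimated from forward spatial
differences of the standardized residuals: per axis,
`lambda = Var(de/daxis) / Var(e)` pooled over subjects and in-mask voxel
pairs, and `FWHM = sqrt(4 ln 2 / lambda)` voxels.  On unsmoothed white
noise this estimator converges to FWHM ≈ 1.18 voxels (lambda = 2), its
known floor.  Resel counts R0..R3 summarize the search region: R0 is the
Euler characteristic of the in-mask cubical complex, R1/R2 weight its edge
and face counts by 1/FWHM per axis, and R3 is the mask volume in
FWHM-cubes.

The voxelwise FWE threshold solves `E[EC(u)] = alpha` where E[EC] is the
expected Euler characteristic of the thresholded Student-t field,
`E[EC(u)] = sum_d R_d * rho_d(u, df)` with the standard t-field EC
densities.  Because rho_3 is negative near u = 0, E[EC] has a mode; the
solver takes the largest root (coarse scan on [0, 50], then bisection to
1e-8).  The final threshold is the smaller of the RFT root and the
Bonferroni threshold `t_isf(alpha / V)`, and never below the uncorrected
single-test threshold.  If E[EC] never reaches alpha the RFT branch is
treated as offering no root and Bonferroni is used.

Clusterwise inference forms clusters above the uncorrected
cluster-defining threshold (default p < 0.001, one-sided) using
18-connectivity (face + edge, the convention of the standard SPM
machinery), then assigns each cluster a familywise p-value from the
Gaussian-random-field extent distribution: with `E[m] = E[EC(u)]`,
`E[N] = R3 * P(T > u)`, `beta = (Gamma(5/2) E[m]/E[N])^(2/3)`,
`P(size >= k resels) = exp(-beta k^(2/3))` and
`p_FWE = 1 - exp(-E[m] P(size >= k))`.  Clusters with `p_FWE < alpha`
(default 0.05) survive.

### Bayesian branch: global shrinkage prior and log posterior odds

The hierarchical model places one global prior on all voxels:
`beta_v ~ N(0, cB)`.  cB (the "prior parameter covariance") is estimated
by pooled method of moments: under the model,
`Var_v(beta_hat) = cB + E[sigma^2]/n` across voxels, so
`cB = max(0, Var_v(beta_hat) - mean_v(resid_var)/n)`.  The estimator is
effectively unbiased at realistic V (bias < 1%, RMSE ≈ 0.002 at
V = 50,000, n = 16, cB = 0.25 over 100 simulations in the test suite).

The conjugate posterior per voxel is Gaussian with precision
`1/cB + n/sigma^2`.  By default sigma^2 is the *pooled* (in-mask mean)
residual variance rather than each voxel's own sample variance: per-voxel
variances are chi-square distributed with few degrees of freedom at small
n, and their lower tail produces spuriously overconfident posteriors
(mean log-odds at an active voxel of ~14 at n = 2 collapsing to ~3 by
n = 5 in our measurements).  Pooling removes that pathology, restores the
monotone accumulation of evidence with sample size that this procedure is
valued for, and mirrors the globally pooled error hyperparameters used by
the second-level Bayesian estimator in the major SPM-style toolbox.
`error_var="voxel"` restores the voxel-specific update for study.

A voxel is declared active when the log posterior odds that its effect
exceeds an effect-size threshold gamma beat a cut tau:
`ln[P(beta_v > gamma | D) / P(beta_v <= gamma | D)] > tau`, computed via
the normal log-CDF and clipped at ±40 (beyond double-precision resolution
of Phi and far past any threshold in use).  Under equal prior odds this
equals the log Bayes factor, so tau is the "logBF" threshold: 3 ≈ strong,
5 ≈ very strong evidence, 10 the tool default.  gamma is expressed in
Cohen's-d units of the prior scale, `gamma = d * sqrt(cB)`, so sqrt(cB)
itself corresponds to d = 1.  The package's guideline defaults are
d = 0.5 and tau = 5.  No cluster-extent filter is applied on this branch
by default (extent 0).

## Synthetic data

`generate_subject_images` emulates second-level *inputs* only: each
subject's image is a shared mean map (spherical blobs of amplitude
`d_true * sigma_between`, hard edges, no partial-volume feathering) plus
an independent Gaussian field, smoothed with an isotropic kernel
(periodic boundaries, so the field is stationary) and rescaled *after*
smoothing so the in-mask SD is exactly `sigma_between` — the smoothness
knob therefore never changes power.  Defaults: 40×48×34 grid at 2 mm
(~65k voxels; origin at (−40, −40, −24) mm so medial-frontal coordinates
like (−4, 48, 12) fall inside the mask), inscribed-ellipsoid mask
(V ≈ 34k), n = 16 subjects, FWHM 3 voxels, sigma_between = 1.

What the generator deliberately does **not** emulate: spatially
structured, brain-wide mean effects.  Real group contrast maps carry
dense anatomical structure, which makes the between-voxel variance of
beta_hat — and hence cB — large relative to sigma^2/n, so the shrinkage
prior is mild and thresholded posterior-odds maps are well populated.
With a single small planted blob, cB is tiny (~f_blob · d_true²), the
posterior is shrunk hard toward zero, and Bayesian counts at tau = 5 are
typically zero even when the blob is clearly present to classical
cluster inference.  Passing tests on this generator therefore validate
the *mechanics* (calibration, conjugacy, monotonicity, protocol
bookkeeping), not the real-data count magnitudes or the relative
sensitivity ordering of the three methods on scanner data — reproducing
those requires the deposited first-level maps, which the pipeline accepts
as a directory of NIfTI files plus a mask.

The perturbation model for robustness studies adds iid Gaussian noise,
in-mask only, with per-image SD equal to `fraction` (default 0.25) times
that image's mean absolute in-mask value — contrast images are signed, so
a plain mean could be ≈ 0 and degenerate the noise scale.

## Evaluation protocols

* **Noise robustness**: each method runs once on the original images and
  on R (default 10) independently perturbed copies; one perturbed dataset
  per replicate is shared across methods so comparisons are paired.
  False alarm = |A_noise \ A_orig| / |A_noise|,
  hit = |A_noise ∩ A_orig| / |A_orig|; a rate with an empty denominator
  is undefined and reported as missing, excluded from summaries.
* **Sample-size sweep**: for each of P (default 10) random subject
  orders, the first n = 2..N images are re-analyzed from scratch —
  smoothness, cB and gamma re-estimated per subset, as rerunning the
  tool on each subset would.  Survived counts per method and the t and
  log-odds values at the voxel nearest a target mm coordinate (default
  (−4, 48, 12)) are recorded.  Classical counts at n = 2 are reported as
  missing: the smoothness estimator requires at least one residual
  degree of freedom beyond the mean (n ≥ 3), and df = 1 classical
  inference is meaningless anyway.

## Numerical choices and degenerate inputs

* Coordinates follow the NIfTI affine convention, 0-based voxel indices,
  mm via the affine; `mm_to_voxel` rounds half away from zero and rejects
  out-of-grid coordinates.
* Volumes are float32 on disk, float64 in memory; NaN marks out-of-mask
  values on output maps.
* Cluster labels are deterministic: ordered by descending size, ties by
  lexicographic peak voxel index.
* cB is clamped at 0; a zero cB raises "degenerate prior" rather than
  silently emitting an empty map (the pipeline records the Bayesian count
  as 0 in that case).
* All randomness flows through `numpy.random.default_rng` seeds carried
  in specs and protocol arguments; identical seeds give bit-identical
  images, orders and tables.

## Problem sizes in the test suite

The suite runs entirely on synthetic data generated at test time: the
FWE calibration uses 100 null datasets on the default grid, the cB
recovery study 100 simulations at V = 50,000, the ordering scenario 20
seeds, and the trajectory study one dataset × 10 subject orders.  The
full suite completes in about a minute on one CPU.

## Known limitations

* The smoothness estimator (forward differences of standardized
  residuals) differs in detail from SPM's `spm_est_smoothness`; RFT
  thresholds can deviate from SPM's on the same data, and voxelwise FWE
  is mildly conservative at FWHM ≈ 3 voxels (observed familywise rate
  ≈ 0.02 at nominal 0.05).
* One-sample designs only; no covariates, two-group or paired designs,
  no nonstationary cluster inference, no permutation/TFCE methods, no
  FDR.
* The `reml` tag on `ShrinkagePrior` is reserved; only the moments
  estimator is implemented.
* The Bayesian branch assumes the global shrinkage prior; it does not
  implement first-level Bayesian estimation or model comparison.
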