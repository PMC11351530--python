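# Methods

## Problem setting

Motor-imagery brain–computer interfaces discriminate mental rehearsal of
movements (e.g. left vs. right hand) from multichannel EEG. The spatial
covariance matrix of a trial — an e×e symmetric positive-definite (SPD)
matrix, e the channel count — is a compact descriptor of the spatial power
distribution that carries the class signal. `micov` implements a pipeline
that (1) estimates trial covariances, (2) converts them to Euclidean
feature vectors by either multiple tangent-space projections (M-TSP) or
Cholesky factorization, and (3) classifies with the gate-generated
functional weight classifier (GG-FWC).

## Covariance estimation and the SPD manifold (`micov.spd`)

Trial covariance is the row-mean-centered sample covariance
`X_c X_cᵀ/(T−1)`, optionally blended with `shrinkage·(tr(C)/e)·I`
(`shrinkage` defaults to 0; no temporal filtering is applied — trials are
taken raw). Degenerate estimates (constant channels, T ≤ e) receive a
diagonal jitter of `1e-10·tr(C)/e`, escalated tenfold until the smallest
eigenvalue is positive, so every downstream consumer may assume strict
positive definiteness.

Matrix square root, logarithm and exponential are computed by
eigendecomposition of the symmetrized input `(A+Aᵀ)/2`; symmetrization
suppresses floating-point asymmetry before `eigh`. The affine-invariant
Fréchet mean uses the standard fixed-point iteration

    M ← M^{1/2} · exp( mean_i log(M^{−1/2} C_i M^{−1/2}) ) · M^{1/2}

initialized at the arithmetic mean, stopped when the Frobenius norm of the
mean tangent vector falls below `tol = 1e-8` (cap `max_iter = 100`, with a
warning and a `converged` flag on the info dict if the cap is hit). The
geodesic distance is `‖log(A^{−1/2} B A^{−1/2})‖_F`. The test suite
cross-checks these primitives against scipy's independent Schur-based
`sqrtm`/`logm`/`expm`, against a direct BFGS minimization of the Fréchet
objective, and against the stationarity equation
`mean_i log(M^{−1/2} C_i M^{−1/2}) = 0` that uniquely characterizes the
mean.

## Feature descriptors (`micov.features`)

**M-TSP.** One Riemannian reference mean per class is fit on the training
covariances. Every trial covariance is projected into the tangent space at
each reference,

    Z_m = Cref_m^{1/2} · log(Cref_m^{−1/2} C Cref_m^{−1/2}) · Cref_m^{1/2},

vectorized by a row-major traversal of the upper triangle (diagonal
included), and the per-class vectors are concatenated in ascending label
order, giving `M·e(e+1)/2` features. The off-diagonal entries are *not*
rescaled by √2; the norm-preserving weighting is available via
`weight_offdiag=True` but is off by default, and all tests exercise the
unweighted form. With two classes and 22 channels the feature vector has
506 components.

**Cholesky.** `C = L Lᵀ` with positive diagonal; the features are the
row-major lower-triangle entries of `L` (`e(e+1)/2` components). This
descriptor is cheaper (no reference fitting) but not affine-invariant; the
tangent features consistently edge it out on the synthetic benchmark below.

## The GG-FWC classifier (`micov.ggfwc`)

The model output is a linear form whose weights are functions of the input:

    o(x) = Σ_{d=0..D} Σ_{r=0..R} w_dr · k_r(x) · x_d,   x_0 = 1, k_0(x) ≡ 1.

Gates `k_r` (r ≥ 1) are unnormalized isotropic Gaussians
`exp(−‖x−c_r‖²/(2δσ_r²))` centered on k-means centroids (k-means++, 10
restarts, seeded); `σ_r²` is the mean squared distance of cluster-r members
to their centroid, with a fallback to the global dispersion (mean squared
distance to the grand mean) for singleton or numerically degenerate
clusters, so no gate has zero width; δ is a free scale factor.

With the change of variables `z_s(x) = k_r(x)·x_d`, `s = r·(D+1)+d`, the
model is an ordinary linear classifier over `(R+1)(D+1)` expanded features,
whose r = 0 block is exactly `(1, x₁, …, x_D)` — a fusion of a linear and a
localized nonlinear classifier. Training is a hinge-loss, L2-penalized
linear maximal-margin fit (regularization parameter `C`) on the expansion,
with no extra intercept: the constant `z_0` column carries the bias, so the
weight vector alone defines the model. Inputs are z-scored with training
statistics (std floored at 1e-12) before both gate construction and margin
training; k-means and RBF widths are scale-sensitive, so standardization is
applied once, up front. Ties at `o(x) = 0` go to the positive class (the
larger label). Models serialize to a single JSON document and round-trip
bit-exactly.

Defaults are `R = 10`, `δ = 10`, `C = 1`, chosen as mid-range values of the
search space below; on the synthetic benchmark accuracy is flat across this
space because the linear block dominates, and per-dataset values should
come from `model_selection.tune`.

## Hyperparameter search (`micov.model_selection`)

(R, δ, C) are tuned by sequential model-based optimization: R integer in
[2, 30], δ continuous on [1, 400] (sampled and modelled log-uniformly,
since it acts multiplicatively on squared widths), C on the fixed grid
{1e-4, …, 1e3}; default budget 300 evaluations. The objective is mean
stratified 5-fold cross-validated accuracy on the training session only —
test sessions are never touched during tuning. After a 10-point random
design, a Gaussian-process surrogate (Matérn 5/2 + white noise, inputs
mapped to the unit cube) proposes each next point by maximizing expected
improvement over a 512-point random candidate pool. One seed drives the
whole run, so a longer budget reproduces a shorter one as its prefix and
the running best is monotone.

## Synthetic generator (`micov.synthetic`)

Each synthetic subject has two class covariance centers: a random SPD base
`B = exp(S)` (S random symmetric, eigenvalue spread O(1)) and its
exponential-map displacement by `class_sep` along the focal rank-one
tangent direction `u uᵀ` (u a random unit spatial direction), so the
geodesic distance between the centers equals `class_sep` exactly. The
rank-one choice mimics the spatially focal power modulation
(event-related desynchronization over motor cortex) that distinguishes
imagery classes — the class difference in real recordings is low-rank,
which is why spatial-filter methods work — rather than a diffuse
perturbation of all e(e+1)/2 covariance coordinates. Per trial, a
covariance is drawn from `Wishart(dof, center/dof)` (mean at the center;
`wishart_dof` sets trial-to-trial dispersion, default 50) and a zero-mean
Gaussian time series with that covariance is emitted. Classes are balanced;
train/test partitions, subject ids and the 4-female/5-male cohort gender
pattern (subjects 1, 2, 4, 6 female) are attached as metadata.

Presets: `ds1_like` — 3 channels, 360 train / 240 test trials, T = 1000
samples per trial; `ds2_like` — 22 channels, 120 train / 120 test trials,
T = 500. Trial lengths correspond to 4 s and 2 s epochs at a nominal
250 Hz, typical motor-imagery cue windows.

What the generator does *not* emulate: 1/f spectra, artifacts (blinks,
EMG), non-stationary drift between sessions, volume-conduction structure
or subject-specific electrode geometry. Passing the synthetic recovery
tests therefore demonstrates that the pipeline recovers class-conditional
covariance structure under the stated noise model — not that any particular
accuracy will be attained on recorded EEG.

At the default `ds2_like` conditions (`class_sep = 1.0`, `wishart_dof =
50`) the M-TSP + GG-FWC test accuracy is ≈ 0.95 (20-seed mean 0.951,
range 0.88–0.98); with `class_sep = 0` it sits at chance. The 120-trial
training session against a 506-dimensional feature space is the binding
constraint: the Riemannian minimum-distance-to-mean oracle reaches ≈ 0.97
under the same conditions, and the remaining gap is margin-estimation noise
at n ≪ D.

## Evaluation and I/O (`micov.io_eval`, `micov.cli`)

Trial archives are plain text: one tab-separated channels × samples matrix
per trial plus a JSON manifest (labels, subject, session roles, gender,
channel names, sampling rate, declared class set). Reading validates the
manifest against the files (count, shapes, label domain) and the round trip
is exact (`%.17e` formatting). Class convention: class 1 = left hand maps
to −1, class 2 = right hand to +1 inside the classifier. Evaluation is
per-subject test accuracy, the across-subject arithmetic mean, and
optional gender-group means with the male − female difference in
percentage points. The `micov` CLI wires the stages together
(`simulate`, `extract`, `train`, `predict`, `tune`, `evaluate`,
`gender-summary`) with a single `--seed` and optional YAML config.

Reading BCI Competition GDF recordings is possible through `mne` as an
optional adapter path (construct a `TrialSet` from epoched arrays); it is
deliberately outside the tested core so that the package builds and tests
with zero downloads.

## Numerical choices and limitations

- Eigendecomposition-based matrix functions are accurate to ~1e-10 relative
  for the conditioning encountered here (condition numbers ≲ 1e6);
  extremely ill-conditioned covariances should be shrunk first.
- `cross_val_score` requires every fold to contain both classes
  (stratified); R must not exceed the training-fold size (the CLI caps the
  search range accordingly).
- The GG-FWC is strictly binary; multiclass problems must be reduced
  externally.
- Acceptance-style end-to-end runs use 10 single-subject replicates and a
  25-evaluation tuning budget — sizes chosen so the whole study re-runs in
  well under a minute while the replicate means are stable to ~0.5
  percentage points.
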