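# micov

Covariance-based classification of motor-imagery EEG: multiple
tangent-space projections (M-TSP) and Cholesky descriptors of trial
covariance matrices, classified with the gate-generated functional weight
classifier (GG-FWC).

Motor-imagery brain–computer interfaces decode which movement a user is
imagining (left vs. right hand) from multichannel EEG. The spatial
covariance matrix `C ∈ SPD(e)` of a trial is a robust descriptor of the
class-dependent spatial power pattern. `micov` is for BCI researchers who
want this pipeline end-to-end — covariance estimation, Riemannian-geometry
feature extraction, a nonlinear-but-linearly-trainable classifier,
Bayesian hyperparameter search, and a seeded synthetic generator so the
whole pipeline is testable without any data download.

## The method

1. **Covariance estimation** — `C(n) = X_c X_cᵀ/(T−1)` per trial, with
   optional shrinkage and an SPD-guaranteeing jitter.
2. **M-TSP features** — one Riemannian (Fréchet) mean `Cref_m` per class;
   each trial is mapped into every class tangent space,

       z_m(n) = upper( Cref_m^{1/2} log(Cref_m^{−1/2} C(n) Cref_m^{−1/2}) Cref_m^{1/2} ),

   and the `M` vectors are concatenated: `M·e(e+1)/2` features.
   Alternatively, **Cholesky features**: the lower-triangular entries of
   `L` in `C = L Lᵀ`.
3. **GG-FWC** — `o(x) = Σ_{d=0..D} Σ_{r=0..R} w_dr k_r(x) x_d` with
   `x_0 = 1`, `k_0 ≡ 1`, and Gaussian RBF gates `k_r` built from k-means
   centroids with δ-scaled dispersions. Via `z_s(x) = k_r(x)·x_d` this is a
   linear model over `(R+1)(D+1)` expanded variables, trained with a
   hinge-loss maximal-margin solver (parameter C).
4. **Hyperparameters** `(R, δ, C)` tuned by Gaussian-process Bayesian
   optimization over R ∈ [2, 30], δ ∈ [1, 400],
   C ∈ {1e-4 … 1e3}, objective = stratified 5-fold CV accuracy.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from micov import features, synthetic
from micov.ggfwc import GGFWC
from micov.io_eval import evaluate

# one synthetic 22-channel subject: 120 train / 120 test trials
ts = synthetic.simulate_trials(synthetic.ds2_like(seed=1))
train, test = ts.subset("train"), ts.subset("test")

cov_tr, cov_te = train.covariances(), test.covariances()
bank = features.fit_reference_bank(cov_tr, train.labels)   # 2 class means
Xtr = features.mtsp_transform(cov_tr, bank)                # (120, 506)
Xte = features.mtsp_transform(cov_te, bank)

model = GGFWC(R=10, delta=10.0, margin_C=1.0, seed=0).fit(Xtr, train.labels)
print(f"test accuracy: {evaluate(model, Xte, test.labels):.3f}")
```

Output:

```
test accuracy: 0.942
```

0.942 is the fraction of the 120 held-out trials whose imagined-movement
class the model recovers; the two synthetic class covariance centers sit at
geodesic distance 1.0, and chance is 0.5.

The same round trip from a shell:

```sh
micov --seed 1 simulate --preset ds2 --out subj01
micov extract subj01 --method mtsp --out-prefix subj01
micov --seed 1 train subj01_train.tsv --out model.json --R 10 --delta 10 --C 1
micov evaluate model.json subj01_test.tsv
```

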