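# Methods

This note documents the models and procedures implemented in `rsldecode`,
the choices made where the design was genuinely open, and what the
synthetic-data fixtures do and do not establish.

## Target semantic space

Binary feature norms (items × features, entries 0/1) are column-mean
centered and converted to a cosine similarity matrix `S` over item rows
(`semantic.build_cosine_rsm`). `S` is a Gram matrix of unit vectors, hence
symmetric positive semi-definite up to rounding; `svd_embed` uses the
symmetric eigendecomposition (identical to the SVD for PSD input), clips
any small negative eigenvalues to zero before taking square roots (a
warning reports the clip magnitude), and returns root-weighted singular
vectors `U = V·D^(1/2)` so that `U Uᵀ` is the rank-r truncation of `S`.
Variance explained is σ_k / Σσ over all (clipped) eigenvalues.

Singular-vector signs are arbitrary, and downstream correlations are
sign-sensitive, so each component is oriented deterministically: the mean
coordinate of animate items is made nonnegative (when domain labels are
available; otherwise the largest-magnitude loading is made positive).

Constant feature columns contribute nothing after centering; they are
retained and flagged rather than dropped, so column indices remain stable.

## Decoder

`RSLDecoder` fits `U = Xβ` with one of three penalties:

* `none` — least squares. A rank-deficient design is an error unless the
  minimum-norm solution is explicitly requested, because a wide `X` admits
  infinitely many interpolants.
* `lasso` — `α‖β‖₁`, elementwise soft-thresholding prox.
* `growl` — `α·Σᵢ wᵢ ρ₍ᵢ₎` on sorted row norms with the linear (OSCAR-style)
  weight sequence `wᵢ = λ + ω(m−i)/(m−1)`. This is the standard two-
  parameter grOWL form: λ is the group-lasso floor (row sparsity), ω the
  decay range (coefficient sharing among correlated features). The prox is
  computed exactly: ordered-weighted-L1 prox on the vector of row norms
  (sort, subtract weights, pool-adjacent-violators projection onto the
  nonincreasing cone, clip at zero, unsort), then row rescaling. The PAVA
  kernel is JIT-compiled when numba is available, with a pure-Python
  fallback.

The solver is FISTA with fixed step `1/L`, `L = σ_max(X)²/n` computed from
the smaller Gram matrix, adaptive restart on objective increase, β
initialized at zero, and stopping when the relative objective change falls
below `tol` (default 1e-8, cap 10,000 iterations). The loss is normalized
by `1/(2n)` so α is comparable across window sizes. Non-convergence
returns the current iterate with `converged_ = False` and a warning.

Predictors are z-scored with training-fold statistics inside the estimator
(raw voltages across electrodes would make a single weight sequence
meaningless); prediction re-applies the stored transform, so
cross-validation cannot leak holdout statistics. No intercept is fit and
targets are not centered — the model is literally `U = Xβ`. A consequence:
a nonzero target mean contributes a constant offset to the Frobenius
tuning criterion that is identical across configurations, and the
correlation-based evaluation metrics are unaffected.

Correctness is cross-checked two ways in the test suite: the prox against
scipy's isotonic regression on random instances, and full fits against
sklearn's coordinate-descent solvers (LASSO; multitask lasso for the ω=0
limit) and an unaccelerated proximal-gradient reference for general ω.

## Model selection

Ten stratified outer folds hold out 10 items each (5 animate + 5
inanimate, exact balance enforced); nine stratified inner folds within
each outer training set score hyperparameter configurations by the
Frobenius norm of holdout prediction error. Search is either an explicit
grid or a successive-halving bracket (η = 3, resource = solver iteration
budget, default 27 configurations sampled log-uniformly from
[1e-4, 1e1]³) — a single-bracket concretization of Hyperband. Exact ties
prefer the smallest α, then the smallest ω.

Two selection rules are exposed. `best` (default) returns the
configuration minimizing mean inner error. `1se` returns the most strongly
regularized configuration (largest α, then ω) within one standard error of
the best — the glmnet convention. The distinction matters for support
recovery: with strong planted signal and many more features than items,
near-unregularized fits predict as well as sparse ones (benign
overparameterization), so the prediction-optimal configuration carries no
information about which features matter; the 1-SE rule restores a sparse,
interpretable model at negligible cost in prediction error, and is what
the support-recovery workflow uses.

## Inference

Permutation nulls rerun the full nested-CV decode with row-permuted
targets (one permutation per run, shared across dimensions and subsets so
statistics have a coherent joint null). Per-subject nulls (default 100)
are resampled into a group null (default 10,000 means of one draw per
subject). One-tailed p = (b+1)/(m+1) with b the count of null values
exceeding the observed statistic. FDR control is Benjamini–Hochberg via
statsmodels (Benjamini–Yekutieli available); within a bundle all
window × dimension × subset p-values are adjusted together. Because
cross-validated correlations are negatively biased under the null,
reported values are centered on their permutation-null means.
Re-tuning hyperparameters inside every permutation is the default
(conservative); reusing the observed run's per-fold configurations is
available for speed.

## Window pipeline

Voltage epochs are averaged over stimulus repetitions (missing repetitions
averaged over what is available, logged), boxcar-downsampled (e.g.,
1000 → 100 Hz via 10 ms boxcars), flattened to items × (electrode, time)
with per-column provenance, and censored: columns, then rows, whose
marginal mean is more than 5 SD of the marginal means from the grand mean
are dropped, with row statistics recomputed after column removal so a wild
cell removed with its column cannot also cost its row. No baseline
correction and no re-referencing are applied. Opening windows grow from
stimulus onset (50, 100, 200, …, 1000 ms); moving windows are 100 ms wide
stepped by 50 ms, the last onset at 900 ms so every window is complete and
equally sized. Evaluation computes Pearson correlations of predicted vs
true coordinates per dimension for all items and per domain, and
similarity-level scores: predicted similarities `ŪŪᵀ` compared row-wise
with the rank-r truncation of the target, per item, within three
comparison scopes (all others / same domain / other domain), averaged over
item groups (all / animate / inanimate). Group aggregation across subjects
is an unweighted mean with SEM.

## Synthetic data: what it emulates, what it does not

`make_synthetic_norms` builds binary norms for 100 items (50 animate, 50
inanimate, three subcategories each): domain-marker features possessed
with subcategory-graded probability (so the dominant component spreads
items *within* domains, as real norms do), subcategory markers (more for
animate subcategories, which are better differentiated in real norming
data), and idiosyncratic Bernoulli features. The resulting spectrum —
first component ≈ 34% of variance, weaker components ≈ 6% and 4% — has the
qualitative shape of real feature-norm similarity matrices (a dominant
domain-separating component, much weaker within-domain components),
though the first component is less dominant than in typical real
norming datasets.

`make_condition_dataset` plants five codes in 24 simulated features (half
signal, half uniform noise over the signal range): a binary domain code
(±1 per domain), single-component copies (oneD-1/2/3), or all three
components with four features each. Additive measurement noise is uniform
on (−h, +h); signal features are unit-variance so h is in signal-SD
units. The default sweep uses 11 half-widths on [0, 16] with 20 runs per
level, a range wide enough that RSA on the weakest one-dimensional codes
visibly decays to a CI covering zero while the binary/dominant codes
remain reliably positive. The noise amplitudes are in arbitrary units; the
sweep's shape, not its scale, is the object of interest.

`make_synthetic_ephys` plants a row-sparse linear code in a 100 × 2000
voltage matrix (20 electrodes × 100 timepoints at 100 Hz): by default 40
signal columns confined to a 150–700 ms band, arranged in near-duplicate
pairs (clean within-group correlation ≥ 0.99, exercising the redundancy
assumption) whose mixing directions have all components bounded away from
zero (the spanning assumption), plus i.i.d. Gaussian noise scaled so that
sd(signal)/sd(noise) equals the requested snr (default 4). Group size 2
was chosen because larger duplicate groups make exact support recovery
ill-posed — any optimizer provably needs only a subset of a
highly-redundant group.

Limitations to keep in mind when generalizing from passing tests: the
noise is i.i.d. (no 1/f spectrum, no artifacts, no inter-electrode
correlation), the planted code is exactly linear and stationary within its
band, and there is no biophysical forward model. One consequence is
quantitative: with i.i.d. noise, equal-weight pattern averaging (RSA) is
close to optimal, so RSA retains a small but nonzero within-domain
correlation wherever RSL succeeds. The RSA-vs-RSL dissociation is
therefore demonstrated as a large ratio (within-domain decoding several
times the RSA rho, which sits near the detection floor) rather than as a
strict null — on real recordings, where noise structure violates RSA's
equal-weighting assumption much more severely, the contrast between the
two methods is starker.

## Reduced problem sizes

Defaults chosen for the bundled studies: simulation sweeps use the printed
5 × 11 × 20 design; permutation nulls in tests use 25 permutations per run
and reduced group-null sizes (the printed 100/10,000 are the package
defaults for real analyses); the support-recovery workflow searches an
8-configuration grid at a 300-iteration tuning budget with a full-budget
refit. These sizes are the package's own test-scale choices and are
configurable.

## Known limitations

* grOWL weight sequences admit variants (linear vs spike-shaped decay);
  the linear OSCAR-style decay used here is the standard two-parameter
  form. Replicating analyses produced with another decay requires matching
  that weight scheme.
* Whether to re-tune hyperparameters inside every permutation is a
  judgment call; both modes are implemented and re-tuning is the
  (conservative) default. The Hyperband concretization is a single
  successive-halving bracket.
* The deposited feature norms and patient recordings are not
  redistributable with this package; external-data checks (e.g., the
  81.1/4.4/4.0% variance split of the deposited similarity matrix) run
  only when the data are placed under `data/external/`.
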